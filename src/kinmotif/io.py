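"""Tab-separated readers and writers for every pipeline artifact.

All matrices travel as long-form TSV with one row per (kinase, residue) and
the nine flank positions as columns labelled ``-5..-1, +1..+4`` (mirroring
the layout of published peptide-array supplementary tables).  Floats are
written with Python's shortest round-tripping representation, so
write -> read -> write is byte-identical.

Site tables arrive as arbitrary-width sequence windows (15-mers with the
acceptor at index 7 being the common phosphoproteomics export convention) and
are canonicalized to the internal 10-symbol -5..+4 window, padding with ``_``
beyond the protein termini.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import (
    CENTER_OFFSET,
    CENTER_SYMBOLS,
    DEFAULT_EXCLUSIONS,
    GAP,
    POSITIONS,
    ROW_ORDER,
)
from .enrichment import DifferentialSite, EnrichmentRow, enrichment_frame
from .errors import FormatError, ValidationError
from .pssm import DensitometryMatrix, Pssm
from .scoring import PhosphoSite

logger = logging.getLogger(__name__)

DELIMITER = "\t"
_POSITION_LABELS = [f"{p:+d}" for p in POSITIONS]


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return str(x)


def _write_frame(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(DELIMITER.join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write(DELIMITER.join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# windows


def canonicalize_window(window: str, center_index: int | None = None) -> str:
    """Trim/pad an export window to the canonical 10 symbols (-5..+4).

    ``center_index`` is the 0-based index of the phospho-acceptor within the
    given window; by default the middle position (``len // 2``).  Positions
    beyond either end become ``_``.  Idempotent on canonical windows.
    """
    if center_index is None:
        center_index = len(window) // 2
        if len(window) == 10:
            center_index = CENTER_OFFSET
    out = []
    for offset in range(-CENTER_OFFSET, 10 - CENTER_OFFSET):
        idx = center_index + offset
        out.append(window[idx] if 0 <= idx < len(window) else GAP)
    return "".join(out)


@dataclass
class SiteTableResult:
    """Sites parsed from a table, plus drop/error accounting.

    ``n_dropped_center`` counts rows whose acceptor is not S/T;
    ``errors`` collects (row number, message) for unparseable rows.
    invariant: len(sites) + n_dropped_center + len(errors) == n_input_rows.
    """

    sites: list = field(default_factory=list)
    n_dropped_center: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)
    n_input_rows: int = 0


def read_site_table(
    path,
    window_column: str = "window",
    fc_column: str | None = None,
    multiplicity_column: str | None = None,
    id_column: str | None = None,
    center_index: int | None = None,
    delimiter: str = DELIMITER,
) -> SiteTableResult:
    """Parse a phosphosite (or differential) table.

    Returns :class:`PhosphoSite` objects, or :class:`DifferentialSite` when
    ``fc_column`` is given.  Rows whose acceptor is not Ser/Thr are dropped
    and counted; rows with illegal symbols are collected as errors.
    """
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if window_column not in df.columns:
        raise FormatError(f"{path}: missing window column {window_column!r}")
    for col in (fc_column, multiplicity_column, id_column):
        if col is not None and col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")

    result = SiteTableResult(n_input_rows=len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        window = canonicalize_window(str(rec[window_column]), center_index)
        if window[CENTER_OFFSET] not in CENTER_SYMBOLS:
            result.n_dropped_center += 1
            continue
        site_id = str(rec[id_column]) if id_column else f"site{i}"
        try:
            site = PhosphoSite(site_id=site_id, window=window)
            if fc_column is not None:
                mult = int(rec[multiplicity_column]) if multiplicity_column else 1
                site = DifferentialSite(
                    site=site, log2fc=float(rec[fc_column]), multiplicity=mult
                )
        except (ValidationError, ValueError) as exc:
            result.errors.append((i, str(exc)))
            continue
        result.sites.append(site)
    if result.n_dropped_center:
        logger.info(
            "%s: dropped %d rows with non-S/T acceptor",
            path, result.n_dropped_center,
        )
    return result


def write_sites(sites: list[PhosphoSite], path) -> None:
    """Write canonical phosphosite windows as TSV."""
    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "window": [s.window for s in sites],
        }
    )
    _write_frame(df, path)


def write_differential(sites: list[DifferentialSite], path) -> None:
    """Write a differential study (window, log2 fc, multiplicity) as TSV."""
    df = pd.DataFrame(
        {
            "site_id": [s.site.site_id for s in sites],
            "window": [s.site.window for s in sites],
            "log2fc": [s.log2fc for s in sites],
            "multiplicity": [s.multiplicity for s in sites],
        }
    )
    _write_frame(df, path)


# ---------------------------------------------------------------------------
# matrices


def _matrix_rows(kinase_id: str, values: pd.DataFrame, extra: dict) -> pd.DataFrame:
    df = values.loc[list(ROW_ORDER), list(POSITIONS)].copy()
    df.columns = _POSITION_LABELS
    df.insert(0, "residue", list(ROW_ORDER))
    df.insert(0, "kinase", kinase_id)
    for name, value in extra.items():
        df[name] = value
    return df


def _split_blocks(df: pd.DataFrame, path) -> list[tuple[str, pd.DataFrame]]:
    required = {"kinase", "residue", *_POSITION_LABELS}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    blocks, seen = [], set()
    for kid, block in df.groupby("kinase", sort=False):
        if kid in seen:
            raise FormatError(f"{path}: duplicate kinase id {kid!r}")
        seen.add(kid)
        rows = set(block["residue"])
        missing_rows = [r for r in ROW_ORDER if r not in rows]
        if missing_rows:
            raise FormatError(
                f"{path}: kinase {kid!r} missing residue rows {missing_rows}"
            )
        if len(block) != len(ROW_ORDER):
            raise FormatError(f"{path}: kinase {kid!r} has duplicate residue rows")
        blocks.append((str(kid), block))
    return blocks


def _block_values(block: pd.DataFrame) -> pd.DataFrame:
    values = block.set_index("residue")[_POSITION_LABELS].astype(float)
    values.columns = list(POSITIONS)
    return values.loc[list(ROW_ORDER)]


def read_densitometry(
    path, randomized_exclusions: frozenset = DEFAULT_EXCLUSIONS,
    s_ctrl: float = 1.0, t_ctrl: float = 1.0,
) -> list[DensitometryMatrix]:
    """Read stacked raw densitometry blocks (22 rows x 9 positions per kinase)."""
    df = pd.read_csv(path, sep=DELIMITER, float_precision="round_trip")
    out = []
    for kid, block in _split_blocks(df, path):
        values = _block_values(block)
        if values.isna().any().any():
            cell = values.stack(future_stack=True)
            bad = cell[cell.isna()].index[0]
            raise FormatError(
                f"{path}: kinase {kid!r} has a non-numeric/missing value at "
                f"row {bad[0]!r}, position {bad[1]}"
            )
        out.append(
            DensitometryMatrix(
                kinase_id=kid, values=values,
                randomized_exclusions=randomized_exclusions,
                s_ctrl=s_ctrl, t_ctrl=t_ctrl,
            )
        )
    return out


def write_densitometry(matrices: list[DensitometryMatrix], path) -> None:
    """Write raw densitometry matrices as stacked long-form TSV."""
    frames = [_matrix_rows(m.kinase_id, m.values, {}) for m in matrices]
    _write_frame(pd.concat(frames, ignore_index=True), path)


def read_pssms(path) -> list[Pssm]:
    """Read normalized PSSMs (matrix rows plus s0/t0/n_randomized columns)."""
    df = pd.read_csv(path, sep=DELIMITER, float_precision="round_trip")
    for col in ("s0", "t0", "n_randomized"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    for kid, block in _split_blocks(df, path):
        n_rand = int(block["n_randomized"].iloc[0])
        exclusions = DEFAULT_EXCLUSIONS if n_rand == 17 else frozenset("STCY")
        out.append(
            Pssm(
                kinase_id=kid,
                matrix=_block_values(block),
                s0=float(block["s0"].iloc[0]),
                t0=float(block["t0"].iloc[0]),
                n_randomized=n_rand,
                randomized_exclusions=exclusions,
            )
        )
    return out


def write_pssms(pssms: list[Pssm], path) -> None:
    """Write PSSMs as stacked long-form TSV with s0/t0/n_randomized columns."""
    frames = [
        _matrix_rows(
            p.kinase_id, p.matrix,
            {"s0": p.s0, "t0": p.t0, "n_randomized": p.n_randomized},
        )
        for p in pssms
    ]
    _write_frame(pd.concat(frames, ignore_index=True), path)


# ---------------------------------------------------------------------------
# enrichment tables & trees


def write_enrichment_table(rows: list[EnrichmentRow], path) -> None:
    """Write enrichment rows sorted by adjusted p, then kinase id."""
    df = enrichment_frame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=["kinase", "side", "a", "b", "c", "d", "haldane",
                     "freq_factor_log2", "p", "adj_p", "excluded", "dominant"]
        )
    _write_frame(df, path)


def read_enrichment_table(path) -> pd.DataFrame:
    """Read an enrichment table back as a DataFrame."""
    return pd.read_csv(path, sep=DELIMITER, float_precision="round_trip")


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + ("" if newick.endswith("\n") else "\n"))
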