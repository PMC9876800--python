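"""Kinase motif-enrichment analysis of differential phosphoproteomics.

Given a table of singly phosphorylated sites with log2 fold changes and a
kinase atlas (PSSMs + reference score distributions), sites are classified as
upregulated (log2 fc >= threshold), downregulated (log2 fc <= -threshold) or
unchanged, and for every kinase a 2x2 contingency table compares how often the
kinase is biochemically favoured (top-15 rank) among regulated versus
unchanged sites.  Enrichment per side is tested with a one-sided Fisher exact
test and adjusted with Benjamini-Hochberg across kinases; the frequency
factor log2[(a/(a+b)) / (c/(c+d))] is the volcano-plot x axis.  Tables with a
zero cell receive the Haldane correction (+0.5 to all four cells) for the
frequency factor; the exact test runs on the raw integer counts.  Kinases
significant on both sides, or depleted on both sides, are excluded; otherwise
the side with the smaller adjusted p is the kinase's dominant side.

The `statsmodels`-style entry point is :class:`KinaseEnrichment`:

>>> results = KinaseEnrichment(sites, atlas).fit()   # doctest: +SKIP
>>> print(results.summary())                         # doctest: +SKIP
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .scoring import (
    Atlas,
    DEFAULT_TOP_K,
    PhosphoSite,
    _check_atlas,
    score_matrix,
)

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_ADJ_P_CUTOFF = 0.1


@dataclass(frozen=True)
class DifferentialSite:
    """A phosphosite with a measured log2 fold change.

    ``multiplicity`` is the number of phospho-residues on the source peptide;
    only singly phosphorylated sites (multiplicity 1) enter the analysis.
    """

    site: PhosphoSite
    log2fc: float
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValidationError(
                f"site {self.site.site_id!r}: multiplicity must be >= 1"
            )


@dataclass
class ClassifiedSites:
    """Partition of retained sites into fold-change classes."""

    up: list[DifferentialSite]
    down: list[DifferentialSite]
    unchanged: list[DifferentialSite]
    n_dropped_multiphospho: int
    n_dropped_duplicate: int

    @property
    def n_retained(self) -> int:
        return len(self.up) + len(self.down) + len(self.unchanged)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = regulated & favoured, b = regulated & not,
    c = unchanged & favoured, d = unchanged & not."""

    a: float
    b: float
    c: float
    d: float
    haldane_applied: bool = False

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int) -> "ContingencyTable":
        """Build from integer counts, applying Haldane (+0.5 to all four
        cells) iff any cell is zero."""
        cells = (a, b, c, d)
        if any(x < 0 for x in cells):
            raise ValidationError("contingency counts must be non-negative")
        if min(cells) == 0:
            return cls(a + 0.5, b + 0.5, c + 0.5, d + 0.5, haldane_applied=True)
        return cls(float(a), float(b), float(c), float(d))

    @property
    def raw_cells(self) -> tuple[int, int, int, int]:
        """Integer counts before the Haldane correction."""
        off = 0.5 if self.haldane_applied else 0.0
        return tuple(int(round(x - off)) for x in (self.a, self.b, self.c, self.d))


@dataclass
class EnrichmentRow:
    """Per-kinase, per-side enrichment statistics."""

    kinase_id: str
    side: str                      # "up" or "down"
    table: ContingencyTable
    freq_factor_log2: float
    p: float
    adj_p: float = 1.0
    excluded: bool = False
    dominant: bool = False


def classify_sites(
    sites: list[DifferentialSite],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> ClassifiedSites:
    """Drop multi-phosphorylated and duplicate sites, then partition by fold change.

    The boundary is regulated: |log2 fc| equal to the threshold counts as
    up/down, strictly smaller as unchanged.  Duplicates are sites with an
    identical canonical window (first occurrence kept).
    """
    if fc_threshold <= 0:
        raise ValidationError("fc_threshold must be positive")
    single = [s for s in sites if s.multiplicity == 1]
    n_multi = len(sites) - len(single)

    seen: set[str] = set()
    retained: list[DifferentialSite] = []
    for s in single:
        if s.site.window in seen:
            continue
        seen.add(s.site.window)
        retained.append(s)
    n_dup = len(single) - len(retained)
    if n_multi or n_dup:
        logger.info(
            "classify_sites: dropped %d multi-phosphorylated and %d duplicate sites",
            n_multi, n_dup,
        )

    up = [s for s in retained if s.log2fc >= fc_threshold]
    down = [s for s in retained if s.log2fc <= -fc_threshold]
    unchanged = [s for s in retained if abs(s.log2fc) < fc_threshold]
    return ClassifiedSites(up, down, unchanged, n_multi, n_dup)


def fisher_one_sided(table: ContingencyTable) -> float:
    """Upper-tail (enrichment) Fisher exact p on the raw integer counts.

    The Haldane correction serves the frequency factor only; the exact test
    requires integer tables, so corrected half-counts are stripped first.
    Degenerate margins return p = 1 with a warning.
    """
    a, b, c, d = table.raw_cells
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate contingency margins; p set to 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def frequency_factor(table: ContingencyTable) -> float:
    """log2 of favoured-site frequency among regulated vs unchanged sites."""
    reg = table.a / (table.a + table.b)
    unch = table.c / (table.c + table.d)
    return float(np.log2(reg / unch))


def bh_adjust(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _favoured_matrix(
    sites: list[PhosphoSite], atlas: Atlas, top_k: int
) -> np.ndarray:
    """Boolean (n_sites, n_kinases): kinase ranks in the site's top k.

    Rank order is percentile desc, log2 score desc, kinase id asc — the same
    deterministic ordering the annotation step uses.
    """
    ids = np.array([p.kinase_id for p, _ in atlas])
    pct, log2 = score_matrix(sites, atlas)
    id_rank = np.argsort(np.argsort(ids))  # ascending-id tie-break key
    order = np.lexsort(
        (np.broadcast_to(id_rank, pct.shape), -log2, -pct), axis=1
    )
    fav = np.zeros(pct.shape, dtype=bool)
    np.put_along_axis(fav, order[:, :top_k], True, axis=1)
    return fav


def run_enrichment(
    sites: list[DifferentialSite],
    atlas: Atlas,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    top_k: int = DEFAULT_TOP_K,
    adj_p_cutoff: float = DEFAULT_ADJ_P_CUTOFF,
) -> list[EnrichmentRow]:
    """Full enrichment analysis; returns two rows (up/down) per atlas kinase."""
    _check_atlas(atlas)
    classified = classify_sites(sites, fc_threshold)
    if not classified.unchanged:
        raise ValidationError(
            "no unchanged sites: enrichment has no reference class"
        )

    ids = [p.kinase_id for p, _ in atlas]
    all_sites = classified.up + classified.down + classified.unchanged
    fav = _favoured_matrix([s.site for s in all_sites], atlas, top_k)
    n_up, n_down = len(classified.up), len(classified.down)
    fav_up = fav[:n_up]
    fav_down = fav[n_up:n_up + n_down]
    fav_unch = fav[n_up + n_down:]

    rows_by_side: dict[str, list[EnrichmentRow]] = {}
    for side, fav_reg, n_reg in (("up", fav_up, n_up), ("down", fav_down, n_down)):
        if n_reg == 0:
            warnings.warn(f"no {side}regulated sites; p = 1 on that side", stacklevel=2)
        side_rows = []
        for k, kid in enumerate(ids):
            a = int(fav_reg[:, k].sum())
            b = n_reg - a
            c = int(fav_unch[:, k].sum())
            d = len(classified.unchanged) - c
            table = ContingencyTable.from_counts(a, b, c, d)
            side_rows.append(
                EnrichmentRow(
                    kinase_id=kid,
                    side=side,
                    table=table,
                    freq_factor_log2=frequency_factor(table),
                    p=fisher_one_sided(table),
                )
            )
        adj = bh_adjust([r.p for r in side_rows])
        for r, ap in zip(side_rows, adj):
            r.adj_p = float(ap)
        rows_by_side[side] = side_rows

    for up_row, down_row in zip(rows_by_side["up"], rows_by_side["down"]):
        both_significant = (
            up_row.adj_p <= adj_p_cutoff and down_row.adj_p <= adj_p_cutoff
        )
        both_depleted = (
            up_row.freq_factor_log2 < 0 and down_row.freq_factor_log2 < 0
        )
        if both_significant or both_depleted:
            up_row.excluded = down_row.excluded = True
        elif up_row.adj_p <= down_row.adj_p:
            up_row.dominant = True
        else:
            down_row.dominant = True

    return rows_by_side["up"] + rows_by_side["down"]


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Long-form DataFrame of enrichment rows, sorted by adjusted p then kinase."""
    df = pd.DataFrame(
        {
            "kinase": [r.kinase_id for r in rows],
            "side": [r.side for r in rows],
            "a": [r.table.a for r in rows],
            "b": [r.table.b for r in rows],
            "c": [r.table.c for r in rows],
            "d": [r.table.d for r in rows],
            "haldane": [r.table.haldane_applied for r in rows],
            "freq_factor_log2": [r.freq_factor_log2 for r in rows],
            "p": [r.p for r in rows],
            "adj_p": [r.adj_p for r in rows],
            "excluded": [r.excluded for r in rows],
            "dominant": [r.dominant for r in rows],
        }
    )
    return df.sort_values(["adj_p", "kinase"], kind="stable").reset_index(drop=True)


class KinaseEnrichment:
    """Model object: a differential phosphoproteomics study against a kinase atlas.

    Parameters
    ----------
    sites
        Differential sites (window + log2 fold change + multiplicity).
    atlas
        (Pssm, BackgroundDistribution) pairs, one per kinase.
    fc_threshold
        |log2 fc| at or above which a site counts as regulated (default 1.5;
        use 0.5 for low-dynamic-range studies).
    top_k
        Kinases per site considered biochemically favoured (default 15).
    adj_p_cutoff
        Adjusted-p significance cutoff used by the both-sides exclusion rule.
    """

    def __init__(
        self,
        sites: list[DifferentialSite],
        atlas: Atlas,
        fc_threshold: float = DEFAULT_FC_THRESHOLD,
        top_k: int = DEFAULT_TOP_K,
        adj_p_cutoff: float = DEFAULT_ADJ_P_CUTOFF,
    ) -> None:
        _check_atlas(atlas)
        self.sites = sites
        self.atlas = atlas
        self.fc_threshold = fc_threshold
        self.top_k = top_k
        self.adj_p_cutoff = adj_p_cutoff

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        atlas: Atlas,
        window_column: str = "window",
        fc_column: str = "log2fc",
        multiplicity_column: str | None = None,
        **kwargs,
    ) -> "KinaseEnrichment":
        """Build from a differential table (canonical 10-symbol windows)."""
        sites = []
        for i, row in frame.iterrows():
            mult = int(row[multiplicity_column]) if multiplicity_column else 1
            sites.append(
                DifferentialSite(
                    site=PhosphoSite(site_id=str(i), window=row[window_column]),
                    log2fc=float(row[fc_column]),
                    multiplicity=mult,
                )
            )
        return cls(sites, atlas, **kwargs)

    def fit(self) -> "KinaseEnrichmentResults":
        rows = run_enrichment(
            self.sites,
            self.atlas,
            fc_threshold=self.fc_threshold,
            top_k=self.top_k,
            adj_p_cutoff=self.adj_p_cutoff,
        )
        return KinaseEnrichmentResults(model=self, rows=rows)


@dataclass
class KinaseEnrichmentResults:
    """Fitted enrichment results: per-kinase statistics and diagnostics."""

    model: KinaseEnrichment
    rows: list[EnrichmentRow]
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    def frame(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = enrichment_frame(self.rows)
        return self._frame

    def dominant(self) -> pd.DataFrame:
        """One row per non-excluded kinase: its dominant side."""
        df = self.frame()
        return df[df["dominant"]].reset_index(drop=True)

    def significant(self, cutoff: float | None = None) -> pd.DataFrame:
        """Dominant rows passing the adjusted-p cutoff with positive enrichment."""
        cutoff = self.model.adj_p_cutoff if cutoff is None else cutoff
        dom = self.dominant()
        return dom[(dom["adj_p"] <= cutoff) & (dom["freq_factor_log2"] > 0)]

    def summary(self) -> str:
        """Human-readable summary table of the dominant-side statistics."""
        dom = self.dominant()
        sig = self.significant()
        lines = [
            "Kinase motif enrichment",
            "=" * 64,
            f"kinases: {len(self.model.atlas)}   "
            f"fc threshold: {self.model.fc_threshold}   "
            f"top-k: {self.model.top_k}   adj-p cutoff: {self.model.adj_p_cutoff}",
            f"significant (dominant side, adj p <= cutoff, enriched): {len(sig)}",
            "-" * 64,
            f"{'kinase':<12}{'side':<6}{'freq_factor_log2':>18}{'p':>12}{'adj_p':>12}",
        ]
        for _, r in dom.head(20).iterrows():
            lines.append(
                f"{r['kinase']:<12}{r['side']:<6}"
                f"{r['freq_factor_log2']:>18.3f}{r['p']:>12.3g}{r['adj_p']:>12.3g}"
            )
        return "\n".join(lines)

    def plot_volcano(self, side: str | None = None, ax=None):
        """Volcano plot: x = log2 frequency factor, y = -log10 adjusted p."""
        import matplotlib.pyplot as plt

        df = self.frame()
        if side is not None:
            df = df[df["side"] == side]
        else:
            df = df[df["dominant"]]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(df["freq_factor_log2"], -np.log10(df["adj_p"]), s=12)
        ax.axhline(-np.log10(self.model.adj_p_cutoff), ls="--", lw=0.8, c="grey")
        ax.axvline(0.0, ls="-", lw=0.8, c="grey")
        ax.set_xlabel("log2 frequency factor")
        ax.set_ylabel("-log10 adjusted p")
        return ax
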