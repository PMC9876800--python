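"""Raw densitometry matrices and their normalization into specificity matrices.

A positional-scanning peptide array read-out is a 22-row x 9-position grid of
spot intensities per kinase.  Normalization converts it to a position-specific
scoring matrix (PSSM) whose randomized-residue entries in each column sum to
one, and attaches the Ser-versus-Thr phospho-acceptor favourabilities
``s0``/``t0`` (the larger of the two is always 1).

The normalization rules, applied in this fixed order:

1. every column is divided by the sum of its *n* randomized residues
   (n = 17 for the standard library, 16 for the PDHK-style library that also
   excludes Tyr);
2. the cysteine row is rescaled by one factor so its median across positions
   equals 1/n (cysteine is present on the array but absent from the
   randomized mixture, so its column-share is not comparable);
3. the Ser and Thr rows at each position are overwritten with the median of
   that position's randomized values (acceptor residues in the flank cannot
   be distinguished from direct phosphorylation of the neighbour, so they are
   set to be neutral);
4. the pThr/pTyr rows receive only the column scaling of step 1.

Acceptor favourability: ``S_S`` and ``S_T`` are the raw S- and T-row sums,
divided by the composition controls ``s_ctrl``/``t_ctrl``, then normalized so
the larger becomes 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alphabet import (
    DEFAULT_EXCLUSIONS,
    POSITIONS,
    ROW_ORDER,
    randomized_residues,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Zero cells are floored to this fraction of their column maximum before
#: normalization, so downstream product scores stay finite.
DEFAULT_PSEUDOCOUNT_SCALE = 1e-6


def _as_frame(values, name: str) -> pd.DataFrame:
    """Coerce to a float DataFrame with canonical row/column order."""
    df = pd.DataFrame(values).astype(float)
    missing_rows = [r for r in ROW_ORDER if r not in df.index]
    if missing_rows:
        raise ValidationError(f"{name}: missing residue rows {missing_rows}")
    try:
        cols = [int(c) for c in df.columns]
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name}: non-integer position labels") from exc
    df.columns = cols
    missing_pos = [p for p in POSITIONS if p not in df.columns]
    if missing_pos:
        raise ValidationError(f"{name}: missing positions {missing_pos}")
    return df.loc[list(ROW_ORDER), list(POSITIONS)]


@dataclass
class DensitometryMatrix:
    """Raw spot intensities for one kinase: 22 residue rows x 9 flank positions.

    Parameters
    ----------
    kinase_id
        Unique kinase identifier.
    values
        DataFrame indexed by the 22-token residue alphabet with the nine
        flank positions as integer columns; non-negative densitometry units.
    randomized_exclusions
        Natural residues absent from the randomized mixture; must contain
        S and T.  ``{S,T,C}`` for the standard library, ``{S,T,C,Y}`` for the
        PDHK-style library.
    s_ctrl, t_ctrl
        Acceptor-composition control constants correcting for the different
        Ser vs Thr content of the central (1:1) and peripheral
        (single-acceptor) library positions.  Default 1.0.
    """

    kinase_id: str
    values: pd.DataFrame
    randomized_exclusions: frozenset = DEFAULT_EXCLUSIONS
    s_ctrl: float = 1.0
    t_ctrl: float = 1.0

    def __post_init__(self) -> None:
        self.values = _as_frame(self.values, f"densitometry {self.kinase_id!r}")
        if (self.values.values < 0).any():
            r, c = np.argwhere(self.values.values < 0)[0]
            raise ValidationError(
                f"densitometry {self.kinase_id!r}: negative value at "
                f"row {ROW_ORDER[r]!r}, position {POSITIONS[c]}"
            )
        self.randomized_exclusions = frozenset(self.randomized_exclusions)
        if not {"S", "T"} <= self.randomized_exclusions:
            raise ValidationError("randomized_exclusions must contain S and T")
        if self.s_ctrl <= 0 or self.t_ctrl <= 0:
            raise ValidationError("s_ctrl and t_ctrl must be positive")

    @property
    def randomized_residues(self) -> tuple[str, ...]:
        return randomized_residues(self.randomized_exclusions)

    @property
    def n_randomized(self) -> int:
        return len(self.randomized_residues)


@dataclass
class Pssm:
    """Normalized specificity matrix plus acceptor favourabilities.

    ``matrix`` holds dimensionless favourabilities; for every position the
    randomized residues sum to 1.  ``s0``/``t0`` are the central Ser/Thr
    favourabilities, normalized so ``max(s0, t0) == 1``.
    """

    kinase_id: str
    matrix: pd.DataFrame
    s0: float
    t0: float
    n_randomized: int = 17
    randomized_exclusions: frozenset = DEFAULT_EXCLUSIONS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = _as_frame(self.matrix, f"pssm {self.kinase_id!r}")
        self.randomized_exclusions = frozenset(self.randomized_exclusions)
        if not (0 < self.s0 <= 1 and 0 < self.t0 <= 1):
            raise ValidationError(
                f"pssm {self.kinase_id!r}: s0/t0 must lie in (0, 1]"
            )

    @property
    def randomized_residues(self) -> tuple[str, ...]:
        return randomized_residues(self.randomized_exclusions)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(self.matrix.columns)

    def validate(self, tol: float = 1e-9) -> None:
        """Check the normalization contract (column sums, max(s0,t0)=1)."""
        sums = self.matrix.loc[list(self.randomized_residues)].sum(axis=0)
        if not np.allclose(sums, 1.0, atol=tol):
            raise ValidationError(
                f"pssm {self.kinase_id!r}: randomized column sums deviate "
                f"from 1 by up to {abs(sums - 1).max():.3g}"
            )
        if abs(max(self.s0, self.t0) - 1.0) > tol:
            raise ValidationError(f"pssm {self.kinase_id!r}: max(s0, t0) != 1")
        if (self.matrix.values <= 0).any():
            raise ValidationError(f"pssm {self.kinase_id!r}: non-positive entries")


def compute_st_favorability(raw: DensitometryMatrix) -> tuple[float, float]:
    """Ser vs Thr acceptor favourability ``(s0, t0)`` from a raw matrix.

    Sums the raw S and T rows, divides by the composition controls, and
    normalizes by the larger of the two, so ``max(s0, t0) == 1``.
    """
    s_sum = float(raw.values.loc["S"].sum())
    t_sum = float(raw.values.loc["T"].sum())
    if s_sum == 0.0 and t_sum == 0.0:
        raise ValidationError(
            f"{raw.kinase_id!r}: S and T rows both sum to zero; "
            "acceptor preference undefined"
        )
    s_adj = s_sum / raw.s_ctrl
    t_adj = t_sum / raw.t_ctrl
    top = max(s_adj, t_adj)
    return s_adj / top, t_adj / top


def normalize_densitometry(
    raw: DensitometryMatrix,
    pseudocount_scale: float = DEFAULT_PSEUDOCOUNT_SCALE,
) -> Pssm:
    """Apply the normalization rules (column sum, Cys median, S/T median) in order."""
    rand = list(raw.randomized_residues)
    n = len(rand)
    m = raw.values.copy()

    # Floor zero cells so products and the cysteine median stay defined.
    col_max = m.max(axis=0)
    if (col_max <= 0).any():
        pos = int(col_max.index[np.argmax(col_max.values <= 0)])
        raise ValidationError(
            f"{raw.kinase_id!r}: position {pos} is entirely zero"
        )
    zeros = m.values == 0.0
    if zeros.any():
        logger.info(
            "%s: flooring %d zero cells to %g x column max",
            raw.kinase_id, int(zeros.sum()), pseudocount_scale,
        )
        floor = np.broadcast_to(
            pseudocount_scale * col_max.values, m.shape
        )
        m = m.mask(m == 0.0, pd.DataFrame(floor, index=m.index, columns=m.columns))

    col_sums = m.loc[rand].sum(axis=0)
    if (col_sums <= 0).any():
        pos = int(col_sums.index[np.argmax(col_sums.values <= 0)])
        raise ValidationError(
            f"{raw.kinase_id!r}: randomized-residue sum at position {pos} is zero"
        )
    m = m / col_sums  # step 1: column normalization

    c_median = float(m.loc["C"].median())
    if c_median <= 0:
        raise ValidationError(f"{raw.kinase_id!r}: cysteine row median is zero")
    m.loc["C"] *= (1.0 / n) / c_median  # step 2: Cys median -> 1/n

    medians = m.loc[rand].median(axis=0)
    m.loc["S"] = medians  # step 3: S/T rows -> position medians
    m.loc["T"] = medians

    s0, t0 = compute_st_favorability(raw)
    return Pssm(
        kinase_id=raw.kinase_id,
        matrix=m,
        s0=s0,
        t0=t0,
        n_randomized=n,
        randomized_exclusions=raw.randomized_exclusions,
        provenance={
            "pseudocount_scale": pseudocount_scale,
            "s_ctrl": raw.s_ctrl,
            "t_ctrl": raw.t_ctrl,
            "n_zero_cells_floored": int(zeros.sum()),
        },
    )


def average_pssm(pssms: list[Pssm], group_id: str = "group") -> Pssm:
    """Element-wise mean matrix (and mean s0/t0) over a cluster of kinases.

    Used for group sequence logos.  The averaged s0/t0 are means of the
    members' values, so ``max(s0, t0)`` may fall below 1.
    """
    if not pssms:
        raise ValidationError("average_pssm: empty group")
    n_set = {p.n_randomized for p in pssms}
    if len(n_set) != 1:
        raise ValidationError("average_pssm: mixed library geometries")
    mean = sum(p.matrix for p in pssms) / len(pssms)
    return replace(
        pssms[0],
        kinase_id=group_id,
        matrix=mean,
        s0=float(np.mean([p.s0 for p in pssms])),
        t0=float(np.mean([p.t0 for p in pssms])),
        provenance={"members": [p.kinase_id for p in pssms]},
    )
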