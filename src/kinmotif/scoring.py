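"""Score phosphosite windows against PSSMs and rank them kinome-wide.

A site's raw score under a kinase is the product of the matrix entries of its
flank residues, times the acceptor favourability (``s0`` for Ser centers,
``t0`` for Thr), scaled by the probability of a random library peptide: each
scored flank position contributes a factor ``n_randomized``, so a flat motif
scores exactly 1 regardless of how many positions were scorable.  Gap (``_``)
and unknown (``X``) positions are skipped.  Phosphorylated flank residues map
to the pThr row (``s``/``t``; pSer selectivity is taken as equivalent to
pThr) or the pTyr row (``y``).

Percentile scores place a site's log2 score within the kinase's score
distribution over a reference phosphoproteome: percentile = 100 x (number of
reference scores <= score) / reference size.  A site is called favourable for
a kinase when its percentile is at least 90 (top 10% of the phosphoproteome),
and a kinase is "biochemically favoured" for a site when it ranks in the
site's top 15 kinases.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np

from .alphabet import (
    CENTER_OFFSET,
    CENTER_SYMBOLS,
    FLANK_SYMBOLS,
    POSITIONS,
    ROW_INDEX,
    WINDOW_LENGTH,
    flank_row,
)
from .errors import ValidationError
from .pssm import Pssm

#: Percentile above which a site counts as favourable for a kinase.
FAVORABLE_PERCENTILE = 90.0
#: Number of top-ranked kinases considered biochemically favoured for a site.
DEFAULT_TOP_K = 15


@dataclass(frozen=True)
class PhosphoSite:
    """A Ser/Thr site as a canonical 10-symbol window (positions -5..+4).

    The acceptor sits at offset 5 and must be S or T (lowercase allowed).
    """

    site_id: str
    window: str
    protein_id: str | None = None
    position: int | None = None  # 1-based residue number in the protein

    def __post_init__(self) -> None:
        w = self.window
        if len(w) != WINDOW_LENGTH:
            raise ValidationError(
                f"site {self.site_id!r}: window must have {WINDOW_LENGTH} "
                f"symbols, got {len(w)}"
            )
        if w[CENTER_OFFSET] not in CENTER_SYMBOLS:
            raise ValidationError(
                f"site {self.site_id!r}: center residue {w[CENTER_OFFSET]!r} "
                "is not S/T"
            )
        for i, sym in enumerate(w):
            if i != CENTER_OFFSET and sym not in FLANK_SYMBOLS:
                raise ValidationError(
                    f"site {self.site_id!r}: illegal symbol {sym!r} at offset {i}"
                )

    @property
    def center(self) -> str:
        """Acceptor residue, uppercased (S or T)."""
        return self.window[CENTER_OFFSET].upper()


@dataclass
class BackgroundDistribution:
    """Sorted log2 scores of a reference phosphoproteome for one kinase."""

    kinase_id: str
    scores: np.ndarray  # ascending log2 scores

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size < 1:
            raise ValidationError(
                f"background {self.kinase_id!r}: empty reference"
            )
        if np.any(np.diff(self.scores) < 0):
            self.scores = np.sort(self.scores)

    @property
    def size(self) -> int:
        return int(self.scores.size)


@dataclass
class SiteAnnotation:
    """Kinome-wide ranking of one site.

    ``ranking`` lists (kinase_id, percentile, log2_score) ordered by
    percentile (desc), ties broken by log2 score (desc) then kinase id (asc).
    """

    site_id: str
    ranking: list[tuple[str, float, float]]
    favoured: list[str]           # top-k kinase ids
    promiscuity_index: int        # kinases above the favourability percentile
    median_percentile: float


# ---------------------------------------------------------------------------
# encoding: windows -> row-index arrays for vectorized scoring

_SKIP = -1


def encode_windows(sites: list[PhosphoSite]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sites as (rows, centers) index arrays.

    ``rows`` is (n_sites, 9) of matrix row indices (-1 where the position is
    skipped); ``centers`` is 1 for Ser acceptors, 0 for Thr.
    """
    rows = np.full((len(sites), len(POSITIONS)), _SKIP, dtype=np.int64)
    centers = np.zeros(len(sites), dtype=np.int64)
    for i, site in enumerate(sites):
        centers[i] = 1 if site.center == "S" else 0
        flank = site.window[:CENTER_OFFSET] + site.window[CENTER_OFFSET + 1:]
        for j, sym in enumerate(flank):
            row = flank_row(sym)
            if row is not None:
                rows[i, j] = ROW_INDEX[row]
    return rows, centers


def _log2_matrix(pssm: Pssm) -> tuple[np.ndarray, float, float]:
    """log2 of (matrix * n_randomized), plus log2 s0/t0."""
    values = pssm.matrix.loc[:, list(POSITIONS)].values
    if (values <= 0).any():
        raise ValidationError(
            f"pssm {pssm.kinase_id!r}: non-positive matrix entry; "
            "normalization contract violated"
        )
    return (
        np.log2(values * pssm.n_randomized),
        float(np.log2(pssm.s0)),
        float(np.log2(pssm.t0)),
    )


def log2_scores(pssm: Pssm, rows: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Vectorized log2 scores for encoded windows under one PSSM."""
    logm, ls0, lt0 = _log2_matrix(pssm)
    picked = logm[rows.clip(min=0), np.arange(rows.shape[1])]
    picked = np.where(rows == _SKIP, 0.0, picked)
    return picked.sum(axis=1) + np.where(centers == 1, ls0, lt0)


def score_site(pssm: Pssm, site: PhosphoSite) -> tuple[float, float]:
    """Raw and log2 score of one site under one PSSM."""
    rows, centers = encode_windows([site])
    log2 = float(log2_scores(pssm, rows, centers)[0])
    return float(2.0 ** log2), log2


def build_background(
    pssm: Pssm, reference: list[PhosphoSite]
) -> BackgroundDistribution:
    """Score a reference phosphoproteome and keep the sorted log2 scores."""
    if not reference:
        raise ValidationError(
            f"build_background {pssm.kinase_id!r}: empty reference"
        )
    rows, centers = encode_windows(reference)
    scores = np.sort(log2_scores(pssm, rows, centers))
    return BackgroundDistribution(kinase_id=pssm.kinase_id, scores=scores)


def percentile_score(bg: BackgroundDistribution, log2_score: float) -> float:
    """Percentile rank: 100 x (#reference scores <= score) / size."""
    count = int(np.searchsorted(bg.scores, log2_score, side="right"))
    return 100.0 * count / bg.size


def percentile_scores(bg: BackgroundDistribution, log2: np.ndarray) -> np.ndarray:
    """Vectorized percentile ranks for an array of log2 scores."""
    counts = np.searchsorted(bg.scores, np.asarray(log2, float), side="right")
    return 100.0 * counts / bg.size


Atlas = list[tuple[Pssm, BackgroundDistribution]]


def _check_atlas(atlas: Atlas) -> None:
    if not atlas:
        raise ValidationError("empty atlas")
    for pssm, bg in atlas:
        if pssm.kinase_id != bg.kinase_id:
            raise ValidationError(
                f"atlas mismatch: pssm {pssm.kinase_id!r} paired with "
                f"background {bg.kinase_id!r}"
            )


def score_matrix(sites: list[PhosphoSite], atlas: Atlas) -> tuple[np.ndarray, np.ndarray]:
    """(percentiles, log2 scores), each (n_sites, n_kinases), in atlas order."""
    _check_atlas(atlas)
    rows, centers = encode_windows(sites)
    log2 = np.empty((len(sites), len(atlas)))
    pct = np.empty_like(log2)
    for k, (pssm, bg) in enumerate(atlas):
        log2[:, k] = log2_scores(pssm, rows, centers)
        pct[:, k] = percentile_scores(bg, log2[:, k])
    return pct, log2


def _rank_order(pct_row: np.ndarray, log2_row: np.ndarray) -> np.ndarray:
    """Kinase order: percentile desc, log2 desc, kinase index asc."""
    idx = np.arange(pct_row.size)
    return np.lexsort((idx, -log2_row, -pct_row))


def annotate_sites(
    sites: list[PhosphoSite],
    atlas: Atlas,
    top_k: int = DEFAULT_TOP_K,
    favourable_percentile: float = FAVORABLE_PERCENTILE,
) -> list[SiteAnnotation]:
    """Kinome-wide annotation of many sites (vectorized over the atlas).

    Atlas kinase ids must be sorted-stable for deterministic tie-breaking;
    ties at equal percentile and score break by kinase id ascending.
    """
    _check_atlas(atlas)
    ids = [p.kinase_id for p, _ in atlas]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate kinase ids in atlas")
    order_by_id = np.argsort(np.array(ids))
    pct, log2 = score_matrix(sites, atlas)
    # reorder columns by kinase id so positional tie-break = id tie-break
    pct, log2 = pct[:, order_by_id], log2[:, order_by_id]
    ids_sorted = [ids[i] for i in order_by_id]

    annotations = []
    for i, site in enumerate(sites):
        order = _rank_order(pct[i], log2[i])
        ranking = [
            (ids_sorted[j], float(pct[i, j]), float(log2[i, j])) for j in order
        ]
        annotations.append(
            SiteAnnotation(
                site_id=site.site_id,
                ranking=ranking,
                favoured=[kid for kid, _, _ in ranking[:top_k]],
                promiscuity_index=int((pct[i] > favourable_percentile).sum()),
                median_percentile=float(median(pct[i])),
            )
        )
    return annotations


def annotate_site(
    site: PhosphoSite,
    atlas: Atlas,
    top_k: int = DEFAULT_TOP_K,
    favourable_percentile: float = FAVORABLE_PERCENTILE,
) -> SiteAnnotation:
    """Annotate a single site (see :func:`annotate_sites`)."""
    return annotate_sites([site], atlas, top_k, favourable_percentile)[0]
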