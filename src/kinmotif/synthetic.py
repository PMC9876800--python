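"""Seeded generators for every artifact the pipeline consumes.

These emulate the statistical structure of the real inputs: peptide-array
densitometry with planted positional preferences under multiplicative
log-normal noise, background phosphoproteomes with configurable residue
frequencies and terminus truncation, substrates sampled position-wise from a
kinase's own PSSM columns, and differential studies with one planted
regulated kinase.  Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import (
    DEFAULT_EXCLUSIONS,
    GAP,
    POSITIONS,
    ROW_ORDER,
    randomized_residues,
)
from .errors import ValidationError
from .enrichment import DifferentialSite
from .pssm import DensitometryMatrix, Pssm, normalize_densitometry
from .scoring import Atlas, PhosphoSite, build_background

#: Human-proteome-like background frequencies of the 20 natural residues
#: (rounded composite values; renormalized on use).
PROTEOME_FREQUENCIES: dict[str, float] = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.053, "V": 0.060, "W": 0.012, "Y": 0.027,
}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class MotifSpec:
    """Recipe for one synthetic kinase motif.

    ``preferences`` maps flank position -> {residue: fold}; folds > 1 are
    favoured, folds in (0, 1) disfavoured.  ``acceptor_bias`` is the target
    (S, T) favourability ratio.  ``sigma`` is the log-normal noise scale of
    the simulated densitometry (natural-log scale).
    """

    kinase_id: str
    preferences: dict[int, dict[str, float]] = field(default_factory=dict)
    acceptor_bias: tuple[float, float] = (1.0, 1.0)
    sigma: float = 0.2
    baseline: float = 1000.0
    randomized_exclusions: frozenset = DEFAULT_EXCLUSIONS

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        for pos, prefs in self.preferences.items():
            if pos not in POSITIONS:
                raise ValidationError(f"preference at non-flank position {pos}")
            for res, fold in prefs.items():
                if res not in ROW_ORDER:
                    raise ValidationError(f"unknown residue {res!r}")
                if fold <= 0:
                    raise ValidationError("fold factors must be positive")
        if min(self.acceptor_bias) <= 0:
            raise ValidationError("acceptor_bias components must be positive")


@dataclass
class ProteomeModel:
    """Background phosphoproteome model.

    Flank residues are i.i.d. from ``frequencies`` (default: uniform over the
    17 randomized residues, matching the library composition; use
    :meth:`proteome_like` for empirical frequencies).  Acceptors are drawn
    S vs T by ``acceptor_ratio``; ``phospho_rate`` is the per-flank-position
    chance of a phosphorylated residue (s/t/y, uniform); a
    ``truncated_fraction`` of windows lose a random stretch at one terminus.
    """

    frequencies: dict[str, float] | None = None
    acceptor_ratio: tuple[float, float] = (0.85, 0.15)  # (S, T)
    phospho_rate: float = 0.0
    truncated_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.frequencies is None:
            rand = randomized_residues()
            self.frequencies = {r: 1.0 / len(rand) for r in rand}
        total = sum(self.frequencies.values())
        if total <= 0:
            raise ValidationError("residue frequencies must sum to > 0")
        self.frequencies = {r: f / total for r, f in self.frequencies.items()}
        for rate in (self.phospho_rate, self.truncated_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        if min(self.acceptor_ratio) < 0 or sum(self.acceptor_ratio) <= 0:
            raise ValidationError("invalid acceptor_ratio")

    @classmethod
    def proteome_like(cls, **kwargs) -> "ProteomeModel":
        """Model with empirical human-proteome residue frequencies."""
        return cls(frequencies=dict(PROTEOME_FREQUENCIES), **kwargs)


def gen_densitometry(spec: MotifSpec, seed=0) -> DensitometryMatrix:
    """Simulate a peptide-array read-out for one motif recipe.

    Cell intensity = baseline x fold factor x log-normal(0, sigma) noise.
    The acceptor bias is planted through the S/T row levels, which the
    normalization step reads back out as s0/t0.
    """
    rng = _rng(seed)
    values = pd.DataFrame(
        spec.baseline, index=list(ROW_ORDER), columns=list(POSITIONS), dtype=float
    )
    for pos, prefs in spec.preferences.items():
        for res, fold in prefs.items():
            values.loc[res, pos] *= fold
    s_bias, t_bias = spec.acceptor_bias
    top = max(s_bias, t_bias)
    values.loc["S"] = spec.baseline * s_bias / top
    values.loc["T"] = spec.baseline * t_bias / top
    if spec.sigma > 0:
        noise = rng.lognormal(0.0, spec.sigma, size=values.shape)
        values = values * noise
    return DensitometryMatrix(
        kinase_id=spec.kinase_id,
        values=values,
        randomized_exclusions=spec.randomized_exclusions,
    )


def _truncate(window: str, rng: np.random.Generator) -> str:
    """Replace a random stretch at one terminus with gap symbols."""
    if rng.random() < 0.5:
        k = int(rng.integers(1, 6))  # up to all 5 N-terminal flanks
        return GAP * k + window[k:]
    k = int(rng.integers(1, 5))  # up to all 4 C-terminal flanks
    return window[:-k] + GAP * k


def gen_background_sites(
    model: ProteomeModel, n: int, seed=0, prefix: str = "bg"
) -> list[PhosphoSite]:
    """Draw ``n`` background phosphosites from a proteome model."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed)
    residues = list(model.frequencies)
    probs = np.array([model.frequencies[r] for r in residues])
    s_p = model.acceptor_ratio[0] / sum(model.acceptor_ratio)

    flanks = rng.choice(len(residues), size=(n, 9), p=probs)
    centers = np.where(rng.random(n) < s_p, "S", "T")
    sites = []
    for i in range(n):
        flank = [residues[j] for j in flanks[i]]
        if model.phospho_rate > 0:
            for j in range(9):
                if rng.random() < model.phospho_rate:
                    flank[j] = rng.choice(["s", "t", "y"])
        window = "".join(flank[:5]) + str(centers[i]) + "".join(flank[5:])
        if model.truncated_fraction > 0 and rng.random() < model.truncated_fraction:
            window = _truncate(window, rng)
        sites.append(PhosphoSite(site_id=f"{prefix}{i}", window=window))
    return sites


def gen_substrates_from_pssm(
    pssm: Pssm, n: int, seed=0, prefix: str = "sub"
) -> list[PhosphoSite]:
    """Sample substrates position-wise from a kinase's own specificity.

    Flank residues are drawn with probability proportional to the PSSM's
    randomized-residue column values; the acceptor is drawn proportional to
    (s0, t0).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed)
    rand = list(pssm.randomized_residues)
    cols = []
    for pos in POSITIONS:
        w = pssm.matrix.loc[rand, pos].values.astype(float)
        cols.append(w / w.sum())
    s_p = pssm.s0 / (pssm.s0 + pssm.t0)

    draws = np.column_stack(
        [rng.choice(len(rand), size=n, p=cols[j]) for j in range(9)]
    )
    centers = np.where(rng.random(n) < s_p, "S", "T")
    sites = []
    for i in range(n):
        flank = [rand[j] for j in draws[i]]
        window = "".join(flank[:5]) + str(centers[i]) + "".join(flank[5:])
        sites.append(PhosphoSite(site_id=f"{prefix}{i}", window=window))
    return sites


def gen_atlas_specs(
    n_kinases: int,
    seed=0,
    n_pref_positions: int = 3,
    fold: float = 15.0,
    sigma: float = 0.1,
) -> list[MotifSpec]:
    """Recipes for a panel of well-separated synthetic kinases.

    Each kinase favours one strong residue at each of ``n_pref_positions``
    randomly chosen flank positions.
    """
    rng = _rng(seed)
    rand = randomized_residues()
    specs = []
    for k in range(n_kinases):
        pos_idx = rng.choice(len(POSITIONS), size=n_pref_positions, replace=False)
        prefs = {
            int(POSITIONS[j]): {str(rng.choice(rand)): fold} for j in pos_idx
        }
        bias = (1.0, float(rng.uniform(0.3, 1.0)))
        if rng.random() < 0.5:
            bias = bias[::-1]
        specs.append(
            MotifSpec(
                kinase_id=f"KIN{k:03d}",
                preferences=prefs,
                acceptor_bias=bias,
                sigma=sigma,
            )
        )
    return specs


def gen_atlas(
    n_kinases: int,
    reference: list[PhosphoSite],
    seed=0,
    **spec_kwargs,
) -> Atlas:
    """Synthetic kinase atlas: normalized PSSMs plus reference backgrounds."""
    rng = _rng(seed)
    specs = gen_atlas_specs(n_kinases, seed=rng, **spec_kwargs)
    atlas: Atlas = []
    for spec in specs:
        pssm = normalize_densitometry(gen_densitometry(spec, seed=rng))
        atlas.append((pssm, build_background(pssm, reference)))
    return atlas


def gen_differential_study(
    atlas: Atlas,
    planted_kinase: str,
    n_background: int = 5000,
    n_planted: int = 200,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.3,
    proteome: ProteomeModel | None = None,
    seed=0,
) -> list[DifferentialSite]:
    """A differential study with one planted regulated kinase.

    Background sites get log2 fc ~ Normal(0, noise_sd); substrates sampled
    from the planted kinase's PSSM get log2 fc ~ Normal(effect, noise_sd).
    All sites are singly phosphorylated.
    """
    planted = {p.kinase_id: p for p, _ in atlas}.get(planted_kinase)
    if planted is None:
        raise ValidationError(f"planted kinase {planted_kinase!r} not in atlas")
    rng = _rng(seed)
    proteome = proteome or ProteomeModel()
    bg = gen_background_sites(proteome, n_background, seed=rng, prefix="bg")
    subs = gen_substrates_from_pssm(planted, n_planted, seed=rng, prefix="planted")
    study = [
        DifferentialSite(site=s, log2fc=float(rng.normal(0.0, noise_sd)))
        for s in bg
    ]
    study += [
        DifferentialSite(site=s, log2fc=float(rng.normal(effect_log2fc, noise_sd)))
        for s in subs
    ]
    return study
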