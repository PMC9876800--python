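"""Residue alphabet and window geometry shared across the package.

The positional-scanning peptide library fixes one residue at one flank
position per spot and randomizes the rest.  Each kinase matrix therefore has
22 residue rows — the 20 natural amino acids plus phosphothreonine (row key
``t``) and phosphotyrosine (row key ``y``) — over nine flank positions
(-5..-1, +1..+4) around a central Ser/Thr phospho-acceptor.
"""

from __future__ import annotations

NATURAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Phospho-residue row keys: pThr and pTyr.  A phosphoserine flank residue is
#: scored on the pThr row (pSer selectivity is taken as equivalent to pThr).
PHOSPHO_ROWS: tuple[str, str] = ("t", "y")

#: Canonical fixed row order of every matrix: A..Y then t, y (22 rows).
ROW_ORDER: tuple[str, ...] = tuple(NATURAL_RESIDUES) + PHOSPHO_ROWS

ROW_INDEX: dict[str, int] = {r: i for i, r in enumerate(ROW_ORDER)}

#: Flank positions scored around the acceptor (position 0 is the acceptor).
POSITIONS: tuple[int, ...] = (-5, -4, -3, -2, -1, 1, 2, 3, 4)

#: Canonical window: 10 symbols, positions -5..+4, acceptor at offset 5.
WINDOW_LENGTH: int = 10
CENTER_OFFSET: int = 5

GAP: str = "_"
UNKNOWN: str = "X"

#: Residues absent from the randomized mixture in the standard library
#: (Ser/Thr are acceptors, Cys is excluded for chemistry).
DEFAULT_EXCLUSIONS: frozenset[str] = frozenset("STC")
#: The customized library used for the PDHK-family kinases also omits Tyr.
PDHK_EXCLUSIONS: frozenset[str] = frozenset("STCY")

#: Symbols allowed at flank offsets of a canonical window.
FLANK_SYMBOLS: frozenset[str] = (
    frozenset(NATURAL_RESIDUES) | {"s", "t", "y", GAP, UNKNOWN}
)
#: Symbols allowed at the acceptor offset (lowercase = measured as phosphorylated).
CENTER_SYMBOLS: frozenset[str] = frozenset("STst")


def randomized_residues(exclusions: frozenset[str] = DEFAULT_EXCLUSIONS) -> tuple[str, ...]:
    """Natural residues present in the degenerate library positions (17 by default)."""
    return tuple(r for r in NATURAL_RESIDUES if r not in exclusions)


def flank_row(symbol: str) -> str | None:
    """Matrix row key for a flank symbol, or ``None`` if the position is skipped.

    Uppercase naturals map to themselves; phospho ``s``/``t`` map to the pThr
    row, ``y`` to the pTyr row; gaps and unknowns are skipped.
    """
    if symbol in (GAP, UNKNOWN):
        return None
    if symbol in ("s", "t"):
        return "t"
    if symbol == "y":
        return "y"
    if symbol in ROW_INDEX and symbol.isupper():
        return symbol
    raise ValueError(f"illegal flank symbol {symbol!r}")
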