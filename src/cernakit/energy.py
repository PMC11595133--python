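"""Nearest-neighbor RNA duplex free-energy model.

Duplex stability is approximated as an initiation penalty plus a sum of
stacked-dinucleotide free energies over consecutive base pairs (the
standard nearest-neighbor decomposition). The shipped table holds Turner-
style DeltaG(37 C) stack parameters, in kcal/mol, for all ordered pairs of
Watson-Crick and G.U wobble pairs; loop and bulge contributions are not
modeled — an alignment gap simply breaks the stack.

A base pair is written as a two-letter string, first the base on strand 1
(read 5'->3'), then its partner on strand 2. A helix is an ordered list of
such pairs along strand 1; the stack term for step (p1, p2) is looked up
as ``stack_energy[(p1, p2)]``.

T and U are equivalent throughout (sequences are stored as DNA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = ["NNEnergyModel", "DEFAULT_MODEL", "duplex_energy", "LEGAL_PAIRS"]

LEGAL_PAIRS = ("AU", "UA", "CG", "GC", "GU", "UG")

# Watson-Crick / Watson-Crick stack free energies, kcal/mol at 37 C
# (Turner 2004 nearest-neighbor set; Xia et al. 1998, Biochemistry 37:14719).
_WC_STACKS = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("UA", "UA"): -0.93,
    ("AU", "CG"): -2.24,
    ("AU", "GC"): -2.08,
    ("UA", "CG"): -2.35,
    ("UA", "GC"): -2.11,
    ("CG", "AU"): -2.11,
    ("CG", "UA"): -2.08,
    ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24,
    ("CG", "CG"): -3.26,
    ("CG", "GC"): -3.42,
    ("GC", "CG"): -2.36,
    ("GC", "GC"): -3.26,
}

# Stacks involving at least one G.U wobble pair (Turner 2004 wobble set;
# Mathews et al. 1999, J Mol Biol 288:911).
_GU_STACKS = {
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("UA", "GU"): -1.27,
    ("UA", "UG"): -1.00,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11,
    ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51,
    ("GU", "AU"): -1.00,
    ("GU", "UA"): -1.36,
    ("GU", "CG"): -2.51,
    ("GU", "GC"): -2.11,
    ("UG", "AU"): -1.27,
    ("UG", "UA"): -0.55,
    ("UG", "CG"): -1.53,
    ("UG", "GC"): -1.41,
    ("GU", "GU"): -0.50,
    ("GU", "UG"): +1.29,
    ("UG", "GU"): -0.30,
    ("UG", "UG"): -0.50,
}

_ALL_STACKS = {**_WC_STACKS, **_GU_STACKS}

DUPLEX_INIT_PENALTY = 4.09  # kcal/mol, duplex initiation (Xia et al. 1998)


@dataclass(frozen=True)
class NNEnergyModel:
    """A nearest-neighbor stack table plus duplex initiation penalty."""

    stack_energy: Mapping[tuple[str, str], float]
    init_penalty: float
    version: str

    def __post_init__(self) -> None:
        for p1 in LEGAL_PAIRS:
            for p2 in LEGAL_PAIRS:
                e = self.stack_energy.get((p1, p2))
                if e is None or not math.isfinite(e):
                    raise ValueError(f"stack table missing or non-finite at ({p1}, {p2})")


DEFAULT_MODEL = NNEnergyModel(
    stack_energy=_ALL_STACKS, init_penalty=DUPLEX_INIT_PENALTY, version="turner2004-wc-gu"
)


def normalize_pair(pair: str) -> str:
    """Upper-case and map T->U so pairs can be given in DNA spelling."""
    return pair.upper().replace("T", "U")


def duplex_energy(pairs: Sequence[str], model: NNEnergyModel = DEFAULT_MODEL) -> float:
    """Free energy (kcal/mol) of a contiguous helix given as ordered pairs.

    Returns ``init_penalty`` alone for a single pair (no stacks) and
    ``+inf`` if any element is not a legal Watson-Crick or G.U pair.

    Parameters
    ----------
    pairs:
        Base pairs along strand 1, 5'->3'; each a two-letter string
        (strand-1 base then strand-2 base), DNA or RNA spelling.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    norm = [normalize_pair(p) for p in pairs]
    if any(p not in LEGAL_PAIRS for p in norm):
        return math.inf
    energy = model.init_penalty
    for p1, p2 in zip(norm, norm[1:]):
        energy += model.stack_energy[(p1, p2)]
    return energy
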