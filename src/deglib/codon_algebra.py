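"""IUPAC degenerate-nucleotide algebra.

A degenerate codon is a 3-letter word over the 15-letter IUPAC nucleotide
alphabet. Synthesized as an equimolar base blend, it represents a uniform
mixture over its Cartesian expansion into concrete codons; translating that
mixture under the standard genetic code gives an expected amino-acid
distribution. These distributions are the atoms from which whole-library
composition targets are assembled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
from Bio.Data import CodonTable
from Bio.Data.IUPACData import ambiguous_dna_values

from .constants import AA_LETTERS, STOP

# The 15 IUPAC DNA letters (Biopython also lists 'X' as a synonym of 'N';
# it is not part of the degenerate-codon alphabet used here).
IUPAC_DNA: dict[str, str] = {
    letter: "".join(sorted(bases))
    for letter, bases in ambiguous_dna_values.items()
    if letter != "X"
}

IUPAC_LETTERS: str = "ACGTRYSWKMBDHVN"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_LETTERS)}


class CodonAlgebraError(ValueError):
    """Invalid degenerate codon or alphabet input."""


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon → residue/STOP translation table."""

    codon_to_aa: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise CodonAlgebraError(
                f"genetic code must have 64 entries, got {len(self.codon_to_aa)}"
            )
        stops = [c for c, a in self.codon_to_aa.items() if a == STOP]
        bad = {a for a in self.codon_to_aa.values()} - set(AA_LETTERS) - {STOP}
        if bad:
            raise CodonAlgebraError(f"non-canonical residue letters in code: {bad}")
        if len(stops) != 3:
            raise CodonAlgebraError(f"expected 3 stop codons, got {len(stops)}")

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


def _standard_code() -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    return GeneticCode(mapping)


STANDARD_CODE: GeneticCode = _standard_code()


@dataclass(frozen=True)
class DegenerateCodon:
    """Three IUPAC letters; coding strand, 5'→3', DNA alphabet."""

    letters: str

    def __post_init__(self) -> None:
        if len(self.letters) != 3:
            raise CodonAlgebraError(
                f"degenerate codon must be 3 letters, got {self.letters!r}"
            )
        for ch in self.letters:
            if ch not in IUPAC_DNA:
                raise CodonAlgebraError(
                    f"invalid IUPAC nucleotide symbol {ch!r} in {self.letters!r}"
                )

    @property
    def size(self) -> int:
        """Number of concrete codons in the expansion (1–64)."""
        n = 1
        for ch in self.letters:
            n *= len(IUPAC_DNA[ch])
        return n

    def __str__(self) -> str:
        return self.letters


@dataclass(frozen=True)
class AADistribution:
    """Probability vector over the 20 residues plus a stop mass leak."""

    freqs: Mapping[str, float]
    stop_prob: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.freqs) - set(AA_LETTERS)
        if bad:
            raise CodonAlgebraError(f"unknown residue letters: {sorted(bad)}")
        total = sum(self.freqs.values()) + self.stop_prob
        if any(v < 0 for v in self.freqs.values()) or self.stop_prob < 0:
            raise CodonAlgebraError("negative probability in distribution")
        if abs(total - 1.0) > 1e-12:
            raise CodonAlgebraError(f"distribution sums to {total!r}, not 1")

    @classmethod
    def from_weights(cls, weights: Mapping[str, float]) -> "AADistribution":
        """Normalize arbitrary non-negative weights over residue letters."""
        total = sum(weights.values())
        if total <= 0:
            raise CodonAlgebraError("weights must have positive sum")
        vec = np.array([weights.get(a, 0.0) for a in AA_LETTERS], float) / total
        # renormalize exactly to dodge float round-off in the invariant
        vec /= vec.sum()
        return cls(dict(zip(AA_LETTERS, vec.tolist())), 0.0)

    def as_vector(self) -> np.ndarray:
        """Length-20 vector in AA_LETTERS order (stop mass excluded)."""
        return np.array([self.freqs.get(a, 0.0) for a in AA_LETTERS], float)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(a for a, p in self.freqs.items() if p > 0)


def expand_codon(codon: DegenerateCodon | str) -> frozenset[str]:
    """Cartesian expansion of a degenerate codon into concrete codons."""
    codon = DegenerateCodon(str(codon))
    return frozenset(
        "".join(bases)
        for bases in itertools.product(*(IUPAC_DNA[ch] for ch in codon.letters))
    )


def codon_aa_distribution(
    codon: DegenerateCodon | str, code: GeneticCode = STANDARD_CODE
) -> AADistribution:
    """Expected translation of an equimolar degenerate codon.

    Each concrete expansion is equiprobable (equimolar base mixes at every
    position), so residue probabilities are simple counts over the expansion.
    """
    expansions = sorted(expand_codon(codon))
    n = len(expansions)
    counts: dict[str, int] = {}
    stops = 0
    for c in expansions:
        aa = code.translate(c)
        if aa == STOP:
            stops += 1
        else:
            counts[aa] = counts.get(aa, 0) + 1
    freqs = {a: k / n for a, k in counts.items()}
    # pad to keep the sum-to-1 invariant exact in binary floating point
    residual = 1.0 - stops / n - sum(freqs.values())
    if freqs and abs(residual) > 0:
        first = next(iter(freqs))
        freqs[first] += residual
    return AADistribution(freqs, stop_prob=stops / n)


def all_degenerate_codons() -> list[DegenerateCodon]:
    """All 15^3 = 3375 degenerate codons in sorted letter order."""
    return [
        DegenerateCodon("".join(t))
        for t in itertools.product(sorted(IUPAC_LETTERS), repeat=3)
    ]


@lru_cache(maxsize=None)
def _pool_cached(alphabet: frozenset[str]) -> tuple[str, ...]:
    pool = []
    for codon in all_degenerate_codons():
        dist = codon_aa_distribution(codon)
        if dist.stop_prob > 0:
            continue
        if dist.support <= alphabet:
            pool.append(codon.letters)
    return tuple(sorted(pool))


def stop_free_codon_pool(alphabet: Iterable[str]) -> list[DegenerateCodon]:
    """Every degenerate codon coding only within ``alphabet`` and never STOP.

    Deterministic sorted order. The pool is the optimizer's move set: any
    template drawn from it has zero expected stop mass by construction.
    """
    alpha = frozenset(alphabet)
    if not alpha:
        raise CodonAlgebraError("alphabet must be non-empty")
    bad = alpha - set(AA_LETTERS)
    if bad:
        raise CodonAlgebraError(f"unknown residue letters in alphabet: {sorted(bad)}")
    return [DegenerateCodon(s) for s in _pool_cached(alpha)]


def pool_to_records(pool: Iterable[DegenerateCodon]) -> list[dict]:
    """Rows for CSV export: codon, residues, probabilities."""
    rows = []
    for codon in pool:
        dist = codon_aa_distribution(codon)
        items = sorted(dist.freqs.items())
        rows.append(
            {
                "codon": codon.letters,
                "residues": "".join(a for a, _ in items),
                "probabilities": ";".join(f"{p:.6g}" for _, p in items),
            }
        )
    return rows
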