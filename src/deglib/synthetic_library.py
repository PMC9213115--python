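"""Seeded sampling of concrete library sequences plus a synthesis/sequencing
error model.

This module is the download-free stand-in for a sequenced library: it draws
concrete DNA reads from a degenerate template (equimolar base choice at every
degenerate position), then corrupts them with independent per-nucleotide
substitutions and read duplication. Substitution errors are what introduce
in-frame stop codons into an otherwise stop-free design; duplication is the
simplest mechanism behind non-unique reads (PCR/optical duplicates). Indels
are deliberately not modeled so reads stay frame-aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .codon_algebra import IUPAC_DNA, STANDARD_CODE, expand_codon
from .constants import STOP
from .library_design import Construct, ConstructLayout, DegenerateTemplate, assemble_construct

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class ErrorModel:
    """Per-nucleotide substitution plus read-duplication model.

    sub_rate: probability each base is substituted (uniformly to one of the
        other three). Default 0.0015 per nt, a typical order of magnitude for
        long-oligo synthesis plus sequencing substitutions; use
        ``calibrate_sub_rate`` to pick the rate that reproduces an observed
        stop-containing read fraction for a given template.
    duplication_rate: probability a read is replaced by a copy of an earlier
        read, emulating the few-percent non-unique reads of amplicon data
        (0.02 leaves ~96% of reads unique).
    """

    sub_rate: float = 0.0015
    duplication_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError("sub_rate must be in [0, 1]")
        if not 0.0 <= self.duplication_rate <= 1.0:
            raise ValueError("duplication_rate must be in [0, 1]")


@dataclass
class SyntheticLibrary:
    """Concrete DNA reads with full provenance for reproducibility."""

    ids: list[str]
    seqs: np.ndarray  # (n_reads, read_len) uint8 array of ASCII bases
    construct: Construct
    provenance: dict = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return int(self.seqs.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.seqs.shape[1])

    def sequences(self) -> list[str]:
        return [s.tobytes().decode() for s in self.seqs]

    def variable_regions(self) -> list[str]:
        """Concatenated variable-region nucleotides of each read."""
        lo1, hi1, lo2, hi2 = _variable_bounds(self.construct)
        joined = np.concatenate([self.seqs[:, lo1:hi1], self.seqs[:, lo2:hi2]], axis=1)
        return [s.tobytes().decode() for s in joined]

    def translated_variable_regions(self) -> list[str]:
        """Variable regions translated to residues, '*' marking stops."""
        return [str(Seq(s).translate()) for s in self.variable_regions()]

    def translated_constructs(self) -> list[str]:
        """Full 105-residue translations (fixed flanks + sampled residues)."""
        return [str(Seq(s).translate()) for s in self.sequences()]


def _variable_bounds(construct: Construct) -> tuple[int, int, int, int]:
    """Nucleotide coordinates of the two variable blocks in the construct."""
    layout = construct.layout
    n = construct.n_variable
    k = layout.split_point(n)
    lo1 = 3 * len(layout.n_tag)
    hi1 = lo1 + 3 * k
    lo2 = hi1 + 3 * len(layout.cassette)
    hi2 = lo2 + 3 * (n - k)
    return lo1, hi1, lo2, hi2


def sample_sequences(
    template: DegenerateTemplate,
    layout: ConstructLayout,
    n: int,
    seed: int,
) -> SyntheticLibrary:
    """Draw ``n`` concrete reads from the degenerate construct.

    Each degenerate position is sampled independently and uniformly over its
    IUPAC base set; fixed positions are copied verbatim. Deterministic for a
    given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    construct = assemble_construct(layout, template)
    rng = np.random.default_rng(seed)
    dna = construct.dna
    length = len(dna)
    out = np.empty((n, length), dtype=np.uint8)
    for j, letter in enumerate(dna):
        choices = IUPAC_DNA[letter]
        if len(choices) == 1:
            out[:, j] = ord(choices)
        else:
            opts = np.frombuffer(choices.encode(), dtype=np.uint8)
            out[:, j] = opts[rng.integers(0, len(opts), size=n)]
    ids = [f"read_{i:06d}" for i in range(n)]
    prov = {
        "template": template.codon_strings(),
        "layout": {"n_tag": layout.n_tag, "cassette": layout.cassette, "c_tag": layout.c_tag},
        "n": n,
        "seed": seed,
        "error_model": None,
    }
    return SyntheticLibrary(ids=ids, seqs=out, construct=construct, provenance=prov)


def apply_errors(lib: SyntheticLibrary, model: ErrorModel) -> SyntheticLibrary:
    """Corrupt a library with substitutions, then inject duplicate reads.

    Each base is substituted with probability ``sub_rate``, uniformly to one
    of the other three bases. Then, in read order, each read is replaced with
    probability ``duplication_rate`` by a copy of a uniformly chosen earlier
    (already final) read. Deterministic given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    seqs = lib.seqs.copy()
    n, length = seqs.shape

    if model.sub_rate > 0:
        mask = rng.random(seqs.shape) < model.sub_rate
        # index of current base in ACGT, shift by 1..3 mod 4 → one of the others
        lut = np.zeros(256, dtype=np.uint8)
        for b, i in BASE_INDEX.items():
            lut[ord(b)] = i
        idx = lut[seqs[mask]]
        shift = rng.integers(1, 4, size=idx.shape[0]).astype(np.uint8)
        seqs[mask] = BASES[(idx + shift) % 4]

    if model.duplication_rate > 0 and n > 1:
        dup = rng.random(n) < model.duplication_rate
        dup[0] = False
        for i in np.nonzero(dup)[0]:
            seqs[i] = seqs[rng.integers(0, i)]

    prov = dict(lib.provenance)
    prov["error_model"] = {
        "sub_rate": model.sub_rate,
        "duplication_rate": model.duplication_rate,
        "seed": model.seed,
    }
    return SyntheticLibrary(
        ids=list(lib.ids), seqs=seqs, construct=lib.construct, provenance=prov
    )


def expected_stop_fraction(template: DegenerateTemplate, sub_rate: float) -> float:
    """Exact probability a sampled read gains ≥1 in-frame stop codon.

    For each template position, every concrete expansion codon c mutates to a
    stop codon s with probability (ε/3)^d (1−ε)^(3−d) where d is the Hamming
    distance; positions are independent, so the read-level probability is
    1 − Π_i (1 − q_i). Substitution-only model, variable region only.
    """
    stops = [c for c, a in STANDARD_CODE.codon_to_aa.items() if a == STOP]
    log_clean = 0.0
    for codon in template.codons:
        expansions = sorted(expand_codon(codon))
        q = 0.0
        for c in expansions:
            for s in stops:
                d = sum(a != b for a, b in zip(c, s))
                q += (sub_rate / 3.0) ** d * (1.0 - sub_rate) ** (3 - d)
        q /= len(expansions)
        log_clean += np.log1p(-q)
    return float(1.0 - np.exp(log_clean))


def calibrate_sub_rate(
    template: DegenerateTemplate, target_stop_fraction: float, tol: float = 1e-10
) -> float:
    """Substitution rate whose model-exact stop incidence matches a target.

    Solves ``expected_stop_fraction(template, ε) = target`` by bisection;
    used to emulate an observed stop-containing read fraction (e.g. the ~12%
    seen in sequenced degenerate-oligo libraries).
    """
    if not 0.0 <= target_stop_fraction < 1.0:
        raise ValueError("target_stop_fraction must be in [0, 1)")
    lo, hi = 0.0, 0.75
    if expected_stop_fraction(template, hi) < target_stop_fraction:
        raise ValueError("target stop fraction unreachable by substitutions")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if expected_stop_fraction(template, mid) < target_stop_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def write_fasta(lib: SyntheticLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(lib.ids, lib.sequences()):
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(lib: SyntheticLibrary, path: str | Path) -> None:
    """FASTQ with constant quality 'I' (Q40) — synthetic reads carry no
    base-call uncertainty of their own."""
    with open(path, "w") as fh:
        qual = "I" * lib.read_length
        for rid, seq in zip(lib.ids, lib.sequences()):
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_provenance(lib: SyntheticLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(lib.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
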