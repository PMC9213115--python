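"""Library validation statistics.

Given translated variable regions (or DNA reads), compute the per-position
composition matrix, RMSE to the design target, uniqueness, stop-containing
fraction, misincorporation of off-alphabet residues and per-position
information content. Sequences carrying an in-frame stop are truncation
products and are excluded from composition statistics; they are accounted
for separately by ``stop_fraction``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codon_algebra import AADistribution
from .constants import AA_LETTERS, STOP
from .library_design import composition_rmse

SYMBOLS = AA_LETTERS + STOP  # 21 columns: residues + stop


class QCError(ValueError):
    pass


@dataclass
class CompositionMatrix:
    """Per-position residue frequencies (positions × 21 symbols)."""

    table: pd.DataFrame  # index: position (0-based), columns: SYMBOLS
    n_sequences: int

    def mean_profile(self) -> AADistribution:
        """Position-averaged composition as a distribution."""
        mean = self.table.mean(axis=0)
        stop = float(mean[STOP])
        freqs = {a: float(mean[a]) for a in AA_LETTERS}
        resid = 1.0 - stop - sum(freqs.values())
        freqs[AA_LETTERS[0]] += resid
        return AADistribution(freqs, stop_prob=stop)


def per_position_composition(proteins: Sequence[str]) -> CompositionMatrix:
    """Column-wise residue frequencies of equal-length sequences."""
    if not proteins:
        raise QCError("no sequences given")
    lengths = {len(p) for p in proteins}
    if len(lengths) != 1:
        raise QCError(f"ragged sequence lengths {sorted(lengths)}; no alignment attempted")
    length = lengths.pop()
    arr = np.frombuffer("".join(proteins).encode(), dtype=np.uint8).reshape(
        len(proteins), length
    )
    counts = np.zeros((length, len(SYMBOLS)), dtype=np.int64)
    for j, sym in enumerate(SYMBOLS):
        counts[:, j] = (arr == ord(sym)).sum(axis=0)
    unknown = counts.sum(axis=1) != len(proteins)
    if unknown.any():
        raise QCError(f"non-canonical symbols at positions {np.nonzero(unknown)[0].tolist()}")
    table = pd.DataFrame(counts / len(proteins), columns=list(SYMBOLS))
    table.index.name = "position"
    return CompositionMatrix(table=table, n_sequences=len(proteins))


def uniqueness_fraction(seqs: Sequence[str]) -> float:
    """Share of sequences whose exact string occurs exactly once."""
    if not seqs:
        raise QCError("no sequences given")
    counts = Counter(seqs)
    singletons = sum(c for c in counts.values() if c == 1)
    return singletons / len(seqs)


def stop_fraction(proteins: Sequence[str]) -> float:
    """Fraction of sequences containing at least one stop symbol."""
    if not proteins:
        raise QCError("no sequences given")
    return sum(STOP in p for p in proteins) / len(proteins)


def misincorporation_rate(
    proteins: Sequence[str],
    alphabet: Iterable[str],
    designed: AADistribution | None = None,
) -> tuple[float, pd.DataFrame]:
    """Off-alphabet residue rate plus per-letter deviation from design.

    The rate counts residues outside ``alphabet`` over all residues of
    stop-free sequences. When the designed composition is supplied the
    returned table also reports |observed − designed| / designed for each
    in-alphabet letter (relative deviation, e.g. a letter
    designed at 0.10 but observed at 0.13 deviates by 0.30).
    """
    alpha = frozenset(alphabet)
    if not alpha <= set(AA_LETTERS):
        raise QCError(f"alphabet letters must be canonical, got {sorted(alpha)}")
    clean = [p for p in proteins if STOP not in p]
    if not clean:
        raise QCError("no stop-free sequences to analyse")
    joined = "".join(clean)
    counts = Counter(joined)
    total = len(joined)
    outside = sum(n for aa, n in counts.items() if aa not in alpha)
    rate = outside / total

    rows = []
    for aa in sorted(alpha):
        obs = counts.get(aa, 0) / total
        row = {"residue": aa, "observed": obs}
        if designed is not None:
            des = designed.freqs.get(aa, 0.0)
            row["designed"] = des
            row["relative_deviation"] = abs(obs - des) / des if des > 0 else np.nan
        rows.append(row)
    return rate, pd.DataFrame(rows).set_index("residue")


def position_information(matrix: CompositionMatrix) -> np.ndarray:
    """Information content per position: R_i = log2(20) − H_i bits.

    Stop mass is excluded and the column renormalized before the entropy is
    taken, matching how a sequence logo treats truncation products.
    """
    freqs = matrix.table[list(AA_LETTERS)].to_numpy(float)
    row_sums = freqs.sum(axis=1, keepdims=True)
    if (row_sums <= 0).any():
        raise QCError("a position carries only stop mass; information undefined")
    p = freqs / row_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -terms.sum(axis=1)
    return np.log2(20.0) - entropy


@dataclass
class QCReport:
    """Aggregate QC statistics of one sequenced/simulated library."""

    rmse_to_target: float
    uniqueness_fraction: float
    stop_fraction: float
    misincorporation_rate: float
    max_single_aa_deviation: float
    per_position_information: list[float]
    n_sequences: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def qc_report(
    dna_variable_regions: Sequence[str],
    proteins: Sequence[str],
    target: AADistribution,
    alphabet: Iterable[str],
    uniqueness_on: str = "dna",
) -> QCReport:
    """Full QC of a library given its variable regions.

    Uniqueness is measured on exact DNA strings by default (the stricter
    criterion); pass ``uniqueness_on='protein'`` for the translated level.
    Composition statistics use stop-free sequences only.
    """
    if uniqueness_on not in ("dna", "protein"):
        raise QCError("uniqueness_on must be 'dna' or 'protein'")
    uniq = uniqueness_fraction(
        dna_variable_regions if uniqueness_on == "dna" else list(proteins)
    )
    stops = stop_fraction(proteins)
    clean = [p for p in proteins if STOP not in p]
    if not clean:
        raise QCError("library has no stop-free sequences")
    matrix = per_position_composition(clean)
    rmse = composition_rmse(matrix.mean_profile(), target)
    mis_rate, table = misincorporation_rate(proteins, alphabet, designed=target)
    max_dev = (
        float(table["relative_deviation"].max())
        if "relative_deviation" in table
        else float("nan")
    )
    info = position_information(matrix)
    return QCReport(
        rmse_to_target=rmse,
        uniqueness_fraction=uniq,
        stop_fraction=stops,
        misincorporation_rate=mis_rate,
        max_single_aa_deviation=max_dev,
        per_position_information=[float(x) for x in info],
        n_sequences=len(proteins),
    )


def logo_matrix(matrix: CompositionMatrix) -> pd.DataFrame:
    """Position × letter frequency table in the layout logo renderers read
    (stop column dropped, rows renormalized)."""
    freqs = matrix.table[list(AA_LETTERS)]
    return freqs.div(freqs.sum(axis=1), axis=0)
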