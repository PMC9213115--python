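"""Theoretical molecular-mass envelope of a combinatorial library.

Positions of a degenerate template are independent, so the construct mass is
a sum of independent per-position residue masses plus the fixed-region mass
and one water. The exact moments follow in closed form; the full envelope is
the convolution of per-position mass distributions on a discrete grid. This
envelope is the comparison target for linear-mode MALDI spectra of ~11 kDa
library products, hence the default 1-Da grid and average (not monoisotopic)
masses.

Discretization uses the lever rule: each residue's point mass is split
between the two adjacent grid bins in proportion to its fractional offset.
This preserves the mean exactly and inflates the variance by at most 1/4 of
a bin per position, keeping the grid moments within half a bin of the
closed-form values even for long templates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .codon_algebra import codon_aa_distribution
from .constants import (
    AVERAGE_RESIDUE_MASS,
    AVERAGE_WATER_MASS,
    MONOISOTOPIC_RESIDUE_MASS,
    MONOISOTOPIC_WATER_MASS,
)
from .library_design import ConstructLayout, DegenerateTemplate


class MassEnvelopeError(ValueError):
    pass


@dataclass(frozen=True)
class MassTable:
    """Residue masses (Da) plus the terminal water mass."""

    residue_mass: Mapping[str, float]
    water: float

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.residue_mass.values()) or self.water <= 0:
            raise MassEnvelopeError("masses must be positive")

    def peptide_mass(self, seq: str) -> float:
        return sum(self.residue_mass[a] for a in seq) + self.water


AVERAGE_MASSES = MassTable(AVERAGE_RESIDUE_MASS, AVERAGE_WATER_MASS)
MONOISOTOPIC_MASSES = MassTable(MONOISOTOPIC_RESIDUE_MASS, MONOISOTOPIC_WATER_MASS)


def _position_mass_distribution(
    codon, masses: MassTable
) -> tuple[np.ndarray, np.ndarray]:
    """Residue masses and probabilities of one degenerate position.

    Stop-codon expansions are excluded and the remaining mass renormalized:
    stop-containing molecules truncate during translation and are not part
    of the full-length product envelope.
    """
    dist = codon_aa_distribution(codon)
    items = [(a, p) for a, p in sorted(dist.freqs.items()) if p > 0]
    if not items:
        raise MassEnvelopeError(f"codon {codon} codes only stops")
    m = np.array([masses.residue_mass[a] for a, _ in items])
    p = np.array([p for _, p in items])
    return m, p / p.sum()


def envelope_moments(
    template: DegenerateTemplate,
    layout: ConstructLayout | None = None,
    masses: MassTable = AVERAGE_MASSES,
) -> tuple[float, float]:
    """Closed-form mean and standard deviation (Da) of the construct mass.

    mean = fixed-region mass + Σ_pos E[m_pos] + water;
    var  = Σ_pos Var[m_pos] by independence of positions.
    With ``layout=None`` the variable region alone (plus water) is treated.
    """
    fixed = 0.0
    if layout is not None:
        for seg in (layout.n_tag, layout.cassette, layout.c_tag):
            fixed += sum(masses.residue_mass[a] for a in seg)
    mean = fixed + masses.water
    var = 0.0
    for codon in template.codons:
        m, p = _position_mass_distribution(codon, masses)
        mu = float(m @ p)
        mean += mu
        var += float((m - mu) ** 2 @ p)
    return mean, float(np.sqrt(var))


@dataclass
class MassDistribution:
    """Probability mass on a uniform Da grid with its exact moments."""

    grid: np.ndarray  # bin centers, Da
    probs: np.ndarray
    mean: float  # closed-form moments of the untruncated envelope
    sd: float
    bin_width: float = 1.0

    def grid_mean(self) -> float:
        return float(self.grid @ self.probs)

    def grid_sd(self) -> float:
        mu = self.grid_mean()
        return float(np.sqrt(((self.grid - mu) ** 2) @ self.probs))

    def grid_skewness(self) -> float:
        mu, sd = self.grid_mean(), self.grid_sd()
        if sd == 0:
            return 0.0
        return float((((self.grid - mu) / sd) ** 3) @ self.probs)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("mass_Da,probability\n")
            for m, p in zip(self.grid, self.probs):
                fh.write(f"{m:.6f},{p:.10e}\n")


_MAX_BINS = 5_000_000


def _lever_deposit(
    offsets: np.ndarray, probs: np.ndarray, n_bins: int
) -> np.ndarray:
    """Spread point masses at fractional bin offsets onto an integer grid."""
    out = np.zeros(n_bins)
    base = np.floor(offsets).astype(int)
    frac = offsets - base
    np.add.at(out, base, probs * (1.0 - frac))
    np.add.at(out, base + 1, probs * frac)
    return out


def envelope_distribution(
    template: DegenerateTemplate,
    layout: ConstructLayout | None = None,
    masses: MassTable = AVERAGE_MASSES,
    bin_width: float = 1.0,
    truncate_sigmas: float = 6.0,
) -> MassDistribution:
    """Full mass envelope by successive convolution on a Da grid.

    Per-position residue-mass distributions are discretized (lever rule) and
    convolved; the result is shifted by the fixed-region + water mass, then
    truncated to mean ± ``truncate_sigmas``·sd and renormalized.
    """
    if bin_width <= 0:
        raise MassEnvelopeError("bin_width must be positive")
    mean, sd = envelope_moments(template, layout, masses)

    max_residue = max(masses.residue_mass.values())
    est_bins = int(len(template.codons) * max_residue / bin_width) + 16
    if est_bins > _MAX_BINS:
        raise MassEnvelopeError("template too long for the requested grid")

    env = np.array([1.0])
    origin = 0.0  # mass of the first bin of `env`, Da
    for codon in template.codons:
        m, p = _position_mass_distribution(codon, masses)
        lo = m.min()
        offsets = (m - lo) / bin_width
        n_bins = int(np.ceil(offsets.max())) + 2
        kernel = _lever_deposit(offsets, p, n_bins)
        env = np.convolve(env, kernel)
        origin += lo

    # shift by fixed-region mass + water, splitting the fractional part
    shift = masses.water
    if layout is not None:
        for seg in (layout.n_tag, layout.cassette, layout.c_tag):
            shift += sum(masses.residue_mass[a] for a in seg)
    origin += shift

    frac = (origin / bin_width) % 1.0
    if frac > 0:
        env = np.convolve(env, np.array([1.0 - frac, frac]))
        origin -= frac * bin_width

    grid = origin + bin_width * np.arange(env.size)

    keep = (grid >= mean - truncate_sigmas * sd - bin_width) & (
        grid <= mean + truncate_sigmas * sd + bin_width
    )
    probs = env[keep]
    grid = grid[keep]
    total = probs.sum()
    if total <= 0:
        raise MassEnvelopeError("truncation removed all probability mass")
    probs = probs / total
    return MassDistribution(grid=grid, probs=probs, mean=mean, sd=sd, bin_width=bin_width)
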