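"""Degenerate-template optimization and construct assembly.

The design problem: choose ``n_variable`` degenerate codons from the
stop-free pool of a residue alphabet so that the mean of their expected
amino-acid distributions matches a target composition. The objective is the
root-mean-square error over all 20 canonical letters (targets are zero
outside the design alphabet, so off-alphabet leakage is penalized).

A simulated-annealing search over single-position codon replacements is
used; any hill-capable stochastic search would do, and the small-instance
brute-force oracle in the test suite pins down correctness.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .codon_algebra import (
    AADistribution,
    DegenerateCodon,
    codon_aa_distribution,
    stop_free_codon_pool,
)
from .constants import AA_LETTERS, ECOLI_PREFERRED_CODON, UNIPROT_FREQUENCIES


class DesignError(ValueError):
    pass


def uniprot_target(alphabet: frozenset[str] | set[str] | None = None) -> AADistribution:
    """UniProt-average composition, optionally restricted and renormalized.

    ``uniprot_target()`` is the full 20-letter (20F) target;
    ``uniprot_target(EARLY_ALPHABET)`` is the 10-letter early-alphabet (10E)
    target, i.e. UniProt frequencies over ASDGLIPTEV renormalized to 1.
    """
    weights = dict(UNIPROT_FREQUENCIES)
    if alphabet is not None:
        alpha = frozenset(alphabet)
        weights = {a: w for a, w in weights.items() if a in alpha}
        if not weights:
            raise DesignError("alphabet shares no letters with the frequency table")
    return AADistribution.from_weights(weights)


def composition_rmse(observed: AADistribution, target: AADistribution) -> float:
    """RMSE between two compositions over all 20 canonical letters."""
    p, t = observed.as_vector(), target.as_vector()
    for name, vec, dist in (("observed", p, observed), ("target", t, target)):
        if abs(vec.sum() + dist.stop_prob - 1.0) > 1e-9:
            raise DesignError(f"{name} distribution is not normalized")
    return float(np.sqrt(np.mean((p - t) ** 2)))


@dataclass(frozen=True)
class ConstructLayout:
    """Fixed construct skeleton around the randomized region.

    Default: N-terminal FLAG tag, central thrombin cleavage cassette
    (ALVPRGS; cleaved between R and G), C-terminal His6 tag. The variable
    region is split evenly around the cassette, giving the 105-residue
    construct with the default 84 variable positions.
    """

    n_tag: str = "DYKDDDDK"
    cassette: str = "ALVPRGS"
    c_tag: str = "HHHHHH"

    def __post_init__(self) -> None:
        for name, seg in (("n_tag", self.n_tag), ("cassette", self.cassette),
                          ("c_tag", self.c_tag)):
            bad = set(seg) - set(AA_LETTERS)
            if bad:
                raise DesignError(f"{name} contains non-canonical letters {bad}")
        if self.cassette.count("LVPRGS") != 1:
            raise DesignError("cassette must contain exactly one LVPRGS motif")

    @property
    def fixed_length(self) -> int:
        return len(self.n_tag) + len(self.cassette) + len(self.c_tag)

    def total_length(self, n_variable: int) -> int:
        return self.fixed_length + n_variable

    def split_point(self, n_variable: int) -> int:
        """Variable codons placed before the cassette (rest go after)."""
        return n_variable // 2


DEFAULT_LAYOUT = ConstructLayout()


@dataclass(frozen=True)
class DesignSpec:
    """What to design: alphabet, composition target, length, skeleton."""

    alphabet: frozenset[str]
    target: AADistribution
    n_variable: int = 84
    layout: ConstructLayout = DEFAULT_LAYOUT

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", frozenset(self.alphabet))
        if self.n_variable < 1:
            raise DesignError("n_variable must be >= 1")
        off = {a for a in AA_LETTERS
               if self.target.freqs.get(a, 0.0) > 0 and a not in self.alphabet}
        if off:
            raise DesignError(f"target puts mass outside the alphabet: {sorted(off)}")


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric-cooling parameters for the template search."""

    t0: float = 0.1
    alpha: float = 0.995
    n_iter: int = 20_000


@dataclass(frozen=True)
class DegenerateTemplate:
    """An ordered degenerate-codon template with its expected composition."""

    codons: tuple[DegenerateCodon, ...]
    expected_profile: AADistribution
    achieved_rmse: float
    objective_trace: tuple[float, ...] = field(default=(), repr=False)

    @property
    def n_variable(self) -> int:
        return len(self.codons)

    def codon_strings(self) -> list[str]:
        return [c.letters for c in self.codons]


def template_profile(codons: list[DegenerateCodon] | tuple[DegenerateCodon, ...]) -> AADistribution:
    """Mean of per-codon expected distributions (positions weighted equally)."""
    vecs = np.array([codon_aa_distribution(c).as_vector() for c in codons])
    stops = np.mean([codon_aa_distribution(c).stop_prob for c in codons])
    mean = vecs.mean(axis=0)
    freqs = dict(zip(AA_LETTERS, mean.tolist()))
    resid = 1.0 - stops - sum(freqs.values())
    freqs[AA_LETTERS[0]] += resid
    return AADistribution(freqs, stop_prob=stops)


def optimize_template(
    spec: DesignSpec,
    seed: int,
    schedule: AnnealingSchedule = AnnealingSchedule(),
) -> DegenerateTemplate:
    """Simulated-annealing search for a composition-matched template.

    Moves replace the codon at a uniformly random position with a uniformly
    random pool codon; geometric cooling. The search starts from the best
    uniform single-codon template and returns the best state ever visited,
    so the result can never be worse than that baseline. Deterministic for
    a given ``seed``.
    """
    pool = stop_free_codon_pool(spec.alphabet)
    if not pool:
        raise DesignError(f"no stop-free codons for alphabet {sorted(spec.alphabet)}")
    rng = np.random.default_rng(seed)

    pool_vecs = np.array([codon_aa_distribution(c).as_vector() for c in pool])
    t_vec = spec.target.as_vector()
    n = spec.n_variable

    def rmse_of_sum(sum_vec: np.ndarray) -> float:
        return float(np.sqrt(np.mean((sum_vec / n - t_vec) ** 2)))

    # baseline: best single codon used uniformly
    base_rmse = np.sqrt(np.mean((pool_vecs - t_vec) ** 2, axis=1))
    start = int(np.argmin(base_rmse))
    state = np.full(n, start, dtype=np.int64)
    sum_vec = pool_vecs[state].sum(axis=0)
    current = rmse_of_sum(sum_vec)

    best_state = state.copy()
    best = current
    trace = [current]

    temp = schedule.t0
    n_pool = len(pool)
    positions = rng.integers(0, n, size=schedule.n_iter)
    candidates = rng.integers(0, n_pool, size=schedule.n_iter)
    uniforms = rng.random(schedule.n_iter)

    for i in range(schedule.n_iter):
        pos, cand = positions[i], candidates[i]
        old = state[pos]
        if cand != old:
            new_sum = sum_vec - pool_vecs[old] + pool_vecs[cand]
            proposal = rmse_of_sum(new_sum)
            delta = proposal - current
            if delta <= 0 or uniforms[i] < math.exp(-delta / temp):
                state[pos] = cand
                sum_vec = new_sum
                current = proposal
                if current < best:
                    best = current
                    best_state = state.copy()
        trace.append(current)
        temp *= schedule.alpha

    codons = tuple(DegenerateCodon(pool[i].letters) for i in best_state)
    profile = template_profile(codons)
    return DegenerateTemplate(
        codons=codons,
        expected_profile=profile,
        achieved_rmse=composition_rmse(profile, spec.target),
        objective_trace=tuple(trace),
    )


def brute_force_template(
    spec: DesignSpec, max_positions: int = 4
) -> tuple[tuple[DegenerateCodon, ...], float]:
    """Exhaustive search over codon multisets; oracle for small instances."""
    if spec.n_variable > max_positions:
        raise DesignError("brute force restricted to small instances")
    pool = stop_free_codon_pool(spec.alphabet)
    t_vec = spec.target.as_vector()
    vecs = np.array([codon_aa_distribution(c).as_vector() for c in pool])
    best_rmse = math.inf
    best_combo: tuple[int, ...] = ()
    for combo in itertools.combinations_with_replacement(range(len(pool)), spec.n_variable):
        mean = vecs[list(combo)].mean(axis=0)
        rmse = float(np.sqrt(np.mean((mean - t_vec) ** 2)))
        if rmse < best_rmse:
            best_rmse = rmse
            best_combo = combo
    return tuple(pool[i] for i in best_combo), best_rmse


@dataclass(frozen=True)
class Construct:
    """Assembled degenerate DNA with its translated skeleton."""

    dna: str
    skeleton: str  # translated fixed residues, 'X' at variable positions
    layout: ConstructLayout
    n_variable: int

    @property
    def translated_length(self) -> int:
        return len(self.skeleton)


def _reverse_translate(peptide: str) -> str:
    return "".join(ECOLI_PREFERRED_CODON[a] for a in peptide)


def assemble_construct(
    layout: ConstructLayout, template: DegenerateTemplate | None
) -> Construct:
    """Emit the full-length degenerate IUPAC DNA for a designed construct.

    Fixed residues are reverse-translated with preferred E. coli codons;
    variable positions carry the template's degenerate codons, split evenly
    around the central cassette. ``template=None`` assembles the bare fixed
    skeleton.
    """
    codons: tuple[DegenerateCodon, ...] = template.codons if template is not None else ()
    n = len(codons)
    k = layout.split_point(n)
    pre = "".join(c.letters for c in codons[:k])
    post = "".join(c.letters for c in codons[k:])
    dna = (
        _reverse_translate(layout.n_tag)
        + pre
        + _reverse_translate(layout.cassette)
        + post
        + _reverse_translate(layout.c_tag)
    )
    skeleton = (
        layout.n_tag + "X" * k + layout.cassette + "X" * (n - k) + layout.c_tag
    )
    return Construct(dna=dna, skeleton=skeleton, layout=layout, n_variable=n)


def locate_cleavage(protein: str) -> int | None:
    """Index of the first residue after the thrombin LVPR↓GS cut, or None.

    Thrombin cleaves between R and G of the LVPRGS motif; the returned
    index is the G, i.e. the start of the C-terminal fragment. The first
    motif occurrence wins.
    """
    i = protein.find("LVPRGS")
    if i < 0:
        return None
    return i + 4
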