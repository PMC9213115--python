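"""Sequence-level physicochemical characterization.

Net charge and isoelectric point follow the standard Henderson–Hasselbalch
treatment: each ionizable group contributes a pH-dependent fractional charge
and the pI is the unique root of the (strictly decreasing) net-charge curve,
found by bisection. Hydropathy is the Kyte–Doolittle GRAVY mean. The
aggregation score is the fraction of residues flagged aggregation-prone by a
pluggable per-residue classifier; the bundled default is a transparent
hydrophobic-window heuristic, not a reimplementation of any published SVM.
Secondary structure handling is limited to the consensus plurality vote over
external 3-state predictions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .constants import AA_LETTERS

ACIDIC = ("C", "D", "E", "Y")
BASIC = ("H", "K", "R")


class PhyschemError(ValueError):
    pass


@dataclass(frozen=True)
class PkaSet:
    """Side-chain and terminal pKa constants (pH units).

    Defaults are the EMBOSS constant set. Published pKa conventions differ
    by a few tenths of a pH unit, which propagates directly into pI values;
    keep the set explicit in any report.
    """

    asp: float = 3.9
    glu: float = 4.1
    cys: float = 8.5
    tyr: float = 10.1
    his: float = 6.5
    lys: float = 10.8
    arg: float = 12.5
    n_term: float = 8.6
    c_term: float = 3.6

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not 0.0 < v < 14.0:
                raise PhyschemError(f"pKa {name}={v} outside (0, 14)")

    def as_dict(self) -> dict[str, float]:
        return {
            "D": self.asp, "E": self.glu, "C": self.cys, "Y": self.tyr,
            "H": self.his, "K": self.lys, "R": self.arg,
            "n_term": self.n_term, "c_term": self.c_term,
        }


DEFAULT_PKA = PkaSet()

# (group key, count key) pairs: acidic groups lose a proton above their pKa,
# basic groups gain one below.
_ACID_KEYS = ("D", "E", "C", "Y", "c_term")
_BASE_KEYS = ("H", "K", "R", "n_term")


def _ionizable_counts(seq: str) -> dict[str, float]:
    bad = set(seq) - set(AA_LETTERS)
    if bad:
        raise PhyschemError(f"non-canonical residues {sorted(bad)}")
    counts = Counter(seq)
    out = {aa: float(counts.get(aa, 0)) for aa in ("D", "E", "C", "Y", "H", "K", "R")}
    out["n_term"] = 1.0
    out["c_term"] = 1.0
    return out


def net_charge(seq: str, pH: float, pka: PkaSet = DEFAULT_PKA) -> float:
    """Net charge (elementary charges) at a given pH, termini included."""
    if not seq:
        raise PhyschemError("empty sequence")
    counts = _ionizable_counts(seq)
    pkas = pka.as_dict()
    pos = sum(counts[k] / (1.0 + 10.0 ** (pH - pkas[k])) for k in _BASE_KEYS)
    neg = sum(counts[k] / (1.0 + 10.0 ** (pkas[k] - pH)) for k in _ACID_KEYS)
    return pos - neg


def _charge_matrix(counts: np.ndarray, pH: np.ndarray, pka: PkaSet) -> np.ndarray:
    """Vectorized net charge; counts is (n_seqs, 9) in key order."""
    pkas = pka.as_dict()
    keys = _BASE_KEYS + _ACID_KEYS
    pk = np.array([pkas[k] for k in keys])
    n_base = len(_BASE_KEYS)
    frac_base = 1.0 / (1.0 + 10.0 ** (pH[:, None] - pk[None, :n_base]))
    frac_acid = 1.0 / (1.0 + 10.0 ** (pk[None, n_base:] - pH[:, None]))
    return (counts[:, :n_base] * frac_base).sum(axis=1) - (
        counts[:, n_base:] * frac_acid
    ).sum(axis=1)


def isoelectric_point(
    seq: str, pka: PkaSet = DEFAULT_PKA, tol: float = 1e-3
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The titration curve is strictly decreasing in pH, so the root is unique
    whenever a sign change exists on the interval.
    """
    return float(isoelectric_points([seq], pka=pka, tol=tol)[0])


def isoelectric_points(
    seqs: Sequence[str], pka: PkaSet = DEFAULT_PKA, tol: float = 1e-3
) -> np.ndarray:
    """Vectorized pI for many sequences (shared bisection sweep)."""
    if not seqs:
        raise PhyschemError("no sequences given")
    key_order = _BASE_KEYS + _ACID_KEYS
    counts = np.array(
        [[_ionizable_counts(s)[k] for k in key_order] for s in seqs], float
    )
    lo = np.zeros(len(seqs))
    hi = np.full(len(seqs), 14.0)
    q_lo = _charge_matrix(counts, lo, pka)
    q_hi = _charge_matrix(counts, hi, pka)
    if (q_lo <= 0).any() or (q_hi >= 0).any():
        raise PhyschemError("no sign change of net charge on [0, 14]")
    # 0.0007 pH resolution after 14 halvings of a 14-unit bracket
    n_steps = int(np.ceil(np.log2(14.0 / tol)))
    for _ in range(n_steps):
        mid = 0.5 * (lo + hi)
        q_mid = _charge_matrix(counts, mid, pka)
        take_hi = q_mid > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    return 0.5 * (lo + hi)


def gravy(seq: str) -> float:
    """Mean Kyte–Doolittle hydropathy (GRAVY) of the sequence."""
    if not seq:
        raise PhyschemError("empty sequence")
    bad = set(seq) - set(AA_LETTERS)
    if bad:
        raise PhyschemError(f"non-canonical residues {sorted(bad)}")
    return sum(KYTE_DOOLITTLE[a] for a in seq) / len(seq)


def hydrophobic_window_flagger(
    seq: str, window: int = 7, threshold: float = 1.0
) -> list[bool]:
    """Default aggregation-prone flagger: centered hydropathy window.

    Residue i is flagged when its centered window (width ``window``,
    truncated at the ends) has mean Kyte–Doolittle hydropathy ≥ ``threshold``
    and contains no charged residue (D/E/K/R). A deliberately transparent
    heuristic; swap in any per-residue classifier for production use.
    """
    half = window // 2
    vals = [KYTE_DOOLITTLE[a] for a in seq]
    flags = []
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        win = seq[lo:hi]
        mean_kd = sum(vals[lo:hi]) / (hi - lo)
        flags.append(mean_kd >= threshold and not any(c in "DEKR" for c in win))
    return flags


def aggregation_score(
    seq: str,
    classifier: Callable[[str], Sequence[bool]] = hydrophobic_window_flagger,
) -> float:
    """Fraction of residues flagged aggregation-prone: flags / length."""
    if not seq:
        raise PhyschemError("empty sequence")
    flags = classifier(seq)
    if len(flags) != len(seq):
        raise PhyschemError(
            f"classifier returned {len(flags)} flags for {len(seq)} residues"
        )
    return sum(bool(f) for f in flags) / len(seq)


@dataclass(frozen=True)
class SSPrediction:
    """Consensus of k per-residue 3-state (H/E/C) predictions."""

    inputs: tuple[str, ...]
    consensus: str

    @property
    def helix_content(self) -> float:
        return self.consensus.count("H") / len(self.consensus)

    @property
    def sheet_content(self) -> float:
        return self.consensus.count("E") / len(self.consensus)


def consensus_ss(predictions: Sequence[str]) -> SSPrediction:
    """Per-position plurality vote over 3-state predictions; ties → C."""
    if not predictions:
        raise PhyschemError("need at least one prediction")
    lengths = {len(p) for p in predictions}
    if len(lengths) != 1:
        raise PhyschemError("predictions have unequal lengths")
    bad = set("".join(predictions)) - set("HEC")
    if bad:
        raise PhyschemError(f"invalid secondary-structure symbols {sorted(bad)}")
    out = []
    for column in zip(*predictions):
        counts = Counter(column)
        top = max(counts.values())
        winners = [s for s, c in counts.items() if c == top]
        out.append(winners[0] if len(winners) == 1 else "C")
    return SSPrediction(inputs=tuple(predictions), consensus="".join(out))


def solubility_category(score: float) -> str:
    """Binary solubility call from an external predictor's scaled score.

    Scores strictly greater than 0.45 are 'soluble'; at or below, 'insoluble'.
    """
    return "soluble" if score > 0.45 else "insoluble"
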