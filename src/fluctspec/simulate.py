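"""Synthetic-data generators with known ground truth.

Two generators drive every estimator and classifier test:

* :func:`simulate_fluctuation_assay` — Luria-Delbrueck mutant counts under a
  deterministic doubling-generation culture model: every cell divides each
  generation, each division mutates with probability mu, and a mutant
  lineage expands with the culture, so a mutant arising g doublings before
  plating contributes a clone of 2**g colonies.

* :func:`simulate_mutant_cohort` — mutant reporter alleles drawn from a
  mixture of the mechanistic processes seen in slippage-prone strains:
  deletions between direct repeats (the inter-repeat segment plus one
  repeat copy is removed), tandem duplications of the same geometry,
  single-base substitutions with a specified six-type spectrum, small
  (1-4 bp) indels, and quasi-palindrome-perfecting insertions.  Each mutant
  carries exactly one event plus its ground-truth label.

:func:`synthetic_reporter` builds a reporter gene emulating the engineered
GC-rich constructs: a 63.8% GC 5' region of 804 bp and a 39% GC native-like
3' region of 966 bp, with a planted 4 bp direct-repeat pair separated by
19 bp (the classic slippage geometry producing a 23 bp deletion) and a
planted length-defect quasi-palindrome whose perfecting event is a
dinucleotide insertion.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluct import FluctuationAssay
from .refseq import (
    DirectRepeatPair,
    GeneReference,
    QuasiPalindrome,
    RegionAnnotation,
    revcomp,
    scan_direct_repeats,
)
from .varcall import VariantCall, apply_variants

__all__ = [
    "CultureModel",
    "ProcessMixture",
    "SimulatedMutant",
    "simulate_fluctuation_assay",
    "simulate_mutant_cohort",
    "synthetic_reporter",
    "perfecting_insertion",
    "PROCESSES",
]

PROCESSES = ("slippage_deletion", "duplication", "sbs", "small_indel", "qp_insertion")

_BASES = "ACGT"


@dataclass(frozen=True)
class CultureModel:
    """Growth/mutation parameters for one simulated culture."""

    n0: int
    n_final: int
    mu: float
    seed: int | None = None

    def __post_init__(self):
        if not (1 <= self.n0 <= self.n_final):
            raise ValueError("need 1 <= n0 <= n_final")
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must be in [0, 1]")


@dataclass
class ProcessMixture:
    """Mixture weights over the mutational processes, plus constraints.

    ``sbs_type_distribution`` is over the six collapsed substitution types.
    ``min_repeat_len`` / ``max_separation`` restrict which direct-repeat
    pairs are eligible slippage substrates.
    """

    weights: dict[str, float]
    sbs_type_distribution: dict[str, float] | None = None
    min_repeat_len: int = 4
    max_separation: int = 50

    def __post_init__(self):
        bad = set(self.weights) - set(PROCESSES)
        if bad:
            raise ValueError(f"unknown processes {sorted(bad)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("weights must sum to a positive value")
        self.weights = {k: v / total for k, v in self.weights.items() if v > 0}
        if self.sbs_type_distribution is None:
            from .spectrum import SBS_TYPES

            self.sbs_type_distribution = {t: 1 / 6 for t in SBS_TYPES}
        s = sum(self.sbs_type_distribution.values())
        self.sbs_type_distribution = {
            k: v / s for k, v in self.sbs_type_distribution.items()
        }


@dataclass
class SimulatedMutant:
    """One mutant allele plus the ground truth that generated it."""

    name: str
    mutant_sequence: str
    process: str
    truth_class: str
    variant: VariantCall
    detail: dict = field(default_factory=dict)


def simulate_fluctuation_assay(
    model: CultureModel,
    n_cultures: int,
    rng: np.random.Generator | None = None,
    label: str = "simulated",
) -> FluctuationAssay:
    """Mutant counts for ``n_cultures`` parallel cultures.

    Growth proceeds by synchronous doublings from n0 to n_final; when the
    ratio is not a power of two the final generation divides only the cells
    needed to reach n_final (those mutants stay single-cell clones).  New
    mutations per generation are Poisson with mean (divisions x mu), so the
    expected total is m = mu * (n_final - n0) and P(count = 0) = exp(-m).
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    counts = []
    for _ in range(n_cultures):
        r = 0
        pop = model.n0
        while pop < model.n_final:
            next_pop = min(2 * pop, model.n_final)
            divisions = next_pop - pop
            k = rng.poisson(divisions * model.mu)
            if k:
                clone = max(1, int(round(model.n_final / next_pop)))
                r += int(k) * clone
            pop = next_pop
        counts.append(r)
    return FluctuationAssay(
        culture_counts=counts, cells_per_culture=float(model.n_final), label=label
    )


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def synthetic_reporter(
    seed: int = 0,
    gc_len: int = 804,
    gc_frac: float = 0.638,
    native_len: int = 966,
    native_frac: float = 0.39,
    fork_direction: str = "leftward-origin",
    name: str = "reporter-GC",
) -> tuple[GeneReference, DirectRepeatPair, QuasiPalindrome]:
    """A synthetic GC-rich reporter with planted slippage and QP substrates.

    Returns (reference, planted_repeat_pair, planted_qp).  The repeat pair
    is 4 bp with 19 bp separation in the GC region; the QP has 8 bp arms
    around a 3 bp loop with the right arm missing an internal dinucleotide,
    so the perfecting event is a 2 bp templated insertion.
    """
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, gc_len, gc_frac) + _random_seq(rng, native_len, native_frac))

    # planted direct repeat: 4 bp copies separated by 19 bp (23 bp slippage deletion)
    rep_unit = "GCCG"
    rep_left = 300  # 1-based
    rep_right = rep_left + len(rep_unit) + 19
    seq[rep_left - 1 : rep_left + 3] = rep_unit
    seq[rep_right - 1 : rep_right + 3] = rep_unit

    # planted quasi-palindrome: left arm 8 bp, loop 3 bp, right arm = revcomp
    # of the left arm with an internal dinucleotide missing
    left_arm = "GACGTTCC"
    loop = "AAA"
    perfect_right = revcomp(left_arm)  # GGAACGTC
    right_arm = perfect_right[:3] + perfect_right[5:]  # drop 2 internal bases
    qp_start = 500
    qp_str = left_arm + loop + right_arm
    seq[qp_start - 1 : qp_start - 1 + len(qp_str)] = qp_str
    qp = QuasiPalindrome(
        left_arm=(qp_start, qp_start + 7),
        right_arm=(qp_start + 11, qp_start + 11 + len(right_arm) - 1),
        loop_len=3,
    )

    ref = GeneReference(
        name=name,
        sequence="".join(seq),
        regions=[
            RegionAnnotation("5prime_GC", 1, gc_len),
            RegionAnnotation("3prime_native", gc_len + 1, gc_len + native_len),
        ],
        fork_direction=fork_direction,
    )
    pair = DirectRepeatPair(left_start=rep_left, right_start=rep_right, length=4)
    l, r = pair.extract(ref.sequence)
    assert l == r == rep_unit
    return ref, pair, qp


def perfecting_insertion(ref_seq: str, qp: QuasiPalindrome) -> VariantCall | None:
    """The insertion that converts a length-defect QP into a perfect palindrome.

    Compares the right arm with the reverse complement of the left arm; if
    the right arm is shorter by d bases and inserting d bases at some offset
    makes them equal, returns the (leftmost) such insertion.  None when no
    single insertion perfects the QP.
    """
    left, right = qp.arm_seqs(ref_seq)
    target = revcomp(left)
    d = len(target) - len(right)
    if d <= 0:
        return None
    for i in range(len(right) + 1):
        if right[:i] + target[i : i + d] + right[i:] == target:
            pos = qp.right_arm[0] - 1 + i  # insert after this 1-based position
            return VariantCall(
                kind="insertion",
                ref_interval=(pos, pos + 1),
                ref_allele="",
                alt_allele=target[i : i + d],
            )
    return None


def simulate_mutant_cohort(
    ref: GeneReference,
    mix: ProcessMixture,
    n: int,
    seed: int | None = None,
    qp_registry: list[QuasiPalindrome] | None = None,
) -> list[SimulatedMutant]:
    """Draw ``n`` single-event mutant alleles from the process mixture."""
    rng = np.random.default_rng(seed)
    seq = ref.sequence
    L = len(seq)

    eligible_pairs = [
        p
        for p in scan_direct_repeats(seq, min_len=mix.min_repeat_len)
        if 1 <= p.separation <= mix.max_separation
    ]
    needs_pairs = any(
        mix.weights.get(p, 0) > 0 for p in ("slippage_deletion", "duplication")
    )
    if needs_pairs and not eligible_pairs:
        raise ValueError("reference has no eligible direct-repeat pair for slippage")

    qps: list[QuasiPalindrome] = list(qp_registry or [])
    qp_events = []
    for qp in qps:
        ins = perfecting_insertion(seq, qp)
        if ins is not None:
            qp_events.append((qp, ins))
    if mix.weights.get("qp_insertion", 0) > 0 and not qp_events:
        raise ValueError(
            "qp_insertion requested but no registered QP is perfectable by insertion"
        )

    process_names = list(mix.weights)
    process_p = np.array([mix.weights[p] for p in process_names])
    sbs_types = list(mix.sbs_type_distribution)
    sbs_p = np.array([mix.sbs_type_distribution[t] for t in sbs_types])

    out = []
    for i in range(n):
        process = process_names[rng.choice(len(process_names), p=process_p)]
        if process == "slippage_deletion":
            pair = eligible_pairs[rng.integers(len(eligible_pairs))]
            s, e = pair.left_start, pair.right_start - 1
            var = VariantCall("deletion", (s, e), seq[s - 1 : e], "")
            truth_class = "DEL_GE5" if var.size >= 5 else "INDEL_LT5"
            detail = {"pair": pair}
        elif process == "duplication":
            pair = eligible_pairs[rng.integers(len(eligible_pairs))]
            s, e = pair.left_start, pair.right_start - 1
            segment = seq[s - 1 : e]
            var = VariantCall("insertion", (e, e + 1), "", segment)
            truth_class = "INS_GE5" if var.size >= 5 else "INDEL_LT5"
            detail = {"pair": pair}
        elif process == "sbs":
            t = sbs_types[rng.choice(len(sbs_types), p=sbs_p)]
            ref_pair = t[:2]  # "AT" or "CG"
            alt_repr = t[3]  # alt base for the A/C representative
            candidates = [
                j for j in range(L) if seq[j] in ref_pair
            ]
            j = candidates[rng.integers(len(candidates))]
            ref_b = seq[j]
            if ref_b in "AC":
                alt_b = alt_repr
            else:
                alt_b = revcomp(alt_repr)
            var = VariantCall("substitution", (j + 1, j + 1), ref_b, alt_b)
            truth_class = "SBS"
            detail = {"sbs_type": t}
        elif process == "small_indel":
            size = int(rng.integers(1, 5))
            if rng.random() < 0.5 and L > size + 2:
                s = int(rng.integers(2, L - size))
                var = VariantCall("deletion", (s, s + size - 1), seq[s - 1 : s - 1 + size], "")
            else:
                p = int(rng.integers(1, L))
                ins = "".join(rng.choice(list(_BASES), size=size))
                var = VariantCall("insertion", (p, p + 1), "", ins)
            truth_class = "INDEL_LT5"
            detail = {"size": size}
        elif process == "qp_insertion":
            qp, var = qp_events[rng.integers(len(qp_events))]
            truth_class = "QP_TEMPLATED"
            detail = {"qp": qp}
        else:  # pragma: no cover
            raise AssertionError(process)

        mutant_seq = apply_variants(seq, [var])
        out.append(
            SimulatedMutant(
                name=f"{ref.name}_mut{i:04d}",
                mutant_sequence=mutant_seq,
                process=process,
                truth_class=truth_class,
                variant=var,
                detail=detail,
            )
        )
    return out
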