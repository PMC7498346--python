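"""Nucleic-acid thermodynamics for probe screening.

Duplex melting temperatures come from the unified nearest-neighbor (NN) model:
per-dinucleotide stack enthalpies/entropies are summed with duplex-initiation
terms, the entropy receives a monovalent-salt correction
``dS += 0.368 (N-1) ln[Na+]``, and

    Tm(K) = 1000 dH / (dS + R ln(CT/x)),   x = 4 (non-self-complementary)

with CT the total strand concentration. Locked-nucleic-acid (LNA) substitutions
raise the duplex Tm; an *approximate* mode adds configurable per-base
increments, while a *refined* mode substitutes perturbed stack parameters where
the configured table provides them. Self-dimer and hairpin screens score
Watson-Crick complementary runs by their stack free-energy sum at 37 deg C;
they are exhaustive over ungapped alignments / single stems and are meant as
screening-grade ranking scores, not full structure prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import ThermoParams, load_thermo_params
from .errors import (
    InvalidAlphabetError,
    MaskError,
    ParameterError,
    SequenceTooShortError,
    UnsupportedConditionError,
)

__all__ = [
    "HybridizationConditions",
    "ThermoResult",
    "LnaMask",
    "DuplexStructure",
    "reverse_complement",
    "nn_thermo",
    "lna_tm",
    "self_dimer",
    "hairpin",
]

R_GAS = 1.987  # cal / (mol K)
T37_K = 310.15

_DNA_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_RNA_TO_DNA_COMP = {"A": "T", "U": "A", "G": "C", "C": "G", "T": "A"}


@dataclass(frozen=True)
class HybridizationConditions:
    """Buffer and assay conditions for Tm prediction.

    Defaults follow common in-situ hybridization practice: 50 mM Na+, no Mg2+,
    25 deg C assay temperature. ``oligo_uM`` is the total strand concentration
    used in the Tm formula (0.25 uM, a common vendor convention).
    """

    sodium_mM: float = 50.0
    magnesium_mM: float = 0.0
    temperature_C: float = 25.0
    oligo_uM: float = 0.25

    def __post_init__(self):
        if self.sodium_mM < 0 or self.magnesium_mM < 0:
            raise ParameterError("ion concentrations must be >= 0")
        if self.oligo_uM <= 0:
            raise ParameterError("oligo_uM must be > 0")

    def equivalent_sodium_M(self, params: ThermoParams) -> float:
        """Monovalent-equivalent salt (mol/L), folding Mg2+ in via sqrt conversion."""
        na_mM = self.sodium_mM + params.mg_equivalent_coefficient * math.sqrt(
            self.magnesium_mM
        )
        return na_mM / 1000.0


@dataclass(frozen=True)
class ThermoResult:
    """NN prediction: Tm (deg C), dH (kcal/mol), dS (cal/(mol K), salt-corrected)
    and dG37 = dH - 310.15 dS / 1000 (kcal/mol). ``mode`` records how LNA
    contributions were handled ("nn", "approximate", "refined", or
    "refined+approximate" when some positions fell back to additive increments).
    """

    tm_C: float
    dH: float
    dS: float
    dG37: float
    mode: str = "nn"


@dataclass(frozen=True)
class LnaMask:
    """Ordered 0-based indices of LNA-modified bases within a backbone."""

    positions: tuple = ()

    def __post_init__(self):
        pos = tuple(sorted(int(p) for p in self.positions))
        if len(set(pos)) != len(pos):
            raise MaskError(f"duplicate LNA positions in {self.positions}")
        object.__setattr__(self, "positions", pos)

    def validate_bounds(self, seq_len: int) -> None:
        for p in self.positions:
            if p < 0 or p >= seq_len:
                raise MaskError(f"LNA position {p} outside sequence of length {seq_len}")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class DuplexStructure:
    """Best-scoring ungapped self-structure.

    ``offset`` is the alignment shift (self-dimer) or the 3' stem-arm start
    (hairpin); ``paired_runs`` lists ``(start, length)`` complementary runs on
    the 5' strand; ``dG`` is the stack-sum free energy at 37 deg C (kcal/mol,
    always <= 0; 0 means no stabilizing structure).
    """

    offset: int = 0
    paired_runs: tuple = ()
    dG: float = 0.0


def _check_dna(seq: str, op: str) -> str:
    s = seq.upper()
    for i, c in enumerate(s):
        if c not in _DNA_COMP:
            raise InvalidAlphabetError(
                f"{op}: invalid DNA character {seq[i]!r} at position {i}"
            )
    return s


def reverse_complement(seq: str, alphabet: str | None = None) -> str:
    """Reverse complement into the DNA alphabet (U pairs as A).

    ``alphabet`` may be "DNA", "RNA", or None to accept either. Case is
    preserved per character; the output is always DNA.
    """
    if not seq:
        raise SequenceTooShortError("reverse_complement: empty sequence")
    if alphabet not in (None, "DNA", "RNA"):
        raise ParameterError(f"alphabet must be 'DNA' or 'RNA', got {alphabet!r}")
    allowed = {"DNA": set("ACGT"), "RNA": set("ACGU")}.get(alphabet, set("ACGTU"))
    out = []
    for i, c in enumerate(seq):
        u = c.upper()
        if u not in allowed:
            raise InvalidAlphabetError(
                f"reverse_complement: invalid character {c!r} at position {i}"
            )
        comp = _RNA_TO_DNA_COMP[u]
        out.append(comp if c.isupper() else comp.lower())
    return "".join(reversed(out))


def _nn_sums(seq: str, params: ThermoParams, lna_positions: tuple = ()) -> tuple:
    """Return (dH, dS, fallback_positions) from initiation + stack sums.

    Stacks whose 5' base is LNA-modified take the perturbed parameters from the
    configured LNA stack table; modified positions without a table entry are
    returned for additive-increment fallback.
    """
    dh, ds = params.init_per_duplex
    for end in (seq[0], seq[-1]):
        t = params.init_terminal_AT if end in "AT" else params.init_terminal_GC
        dh += t[0]
        ds += t[1]
    if seq == "".join(_DNA_COMP[c] for c in reversed(seq)):  # self-complementary
        dh += params.init_symmetry[0]
        ds += params.init_symmetry[1]
    lna = set(lna_positions)
    fallback = []
    for i in range(len(seq) - 1):
        h, s = params.stacks[seq[i : i + 2]]
        if i in lna:
            pert = params.lna_stacks.get(seq[i])
            if pert is None:
                fallback.append(i)
            else:
                h += pert[0]
                s += pert[1]
        dh += h
        ds += s
    # a terminal 3' LNA has no downstream stack; treat it additively
    if len(seq) - 1 in lna:
        fallback.append(len(seq) - 1)
    return dh, ds, tuple(fallback)


def _tm_from_sums(dh: float, ds: float, seq: str, cond: HybridizationConditions,
                  params: ThermoParams) -> tuple:
    na_M = cond.equivalent_sodium_M(params)
    if na_M <= 0:
        raise UnsupportedConditionError(
            "NN salt correction requires a positive monovalent-equivalent "
            f"cation concentration (got Na {cond.sodium_mM} mM, Mg {cond.magnesium_mM} mM)"
        )
    ds_salt = ds + params.salt_entropy_coefficient * (len(seq) - 1) * math.log(na_M)
    self_comp = seq == "".join(_DNA_COMP[c] for c in reversed(seq))
    x = 1.0 if self_comp else 4.0
    ct = cond.oligo_uM * 1e-6
    tm_C = 1000.0 * dh / (ds_salt + R_GAS * math.log(ct / x)) - 273.15
    return tm_C, ds_salt


def nn_thermo(seq: str, cond: HybridizationConditions | None = None,
              params: ThermoParams | None = None) -> ThermoResult:
    """Unified NN Tm/dH/dS/dG37 for an unmodified DNA duplex."""
    cond = cond or HybridizationConditions()
    params = params or load_thermo_params()
    s = _check_dna(seq, "nn_thermo")
    if len(s) < 8:
        raise SequenceTooShortError(
            f"nn_thermo requires length >= 8, got {len(s)}"
        )
    dh, ds, _ = _nn_sums(s, params)
    tm_C, ds_salt = _tm_from_sums(dh, ds, s, cond, params)
    return ThermoResult(
        tm_C=tm_C, dH=dh, dS=ds_salt, dG37=dh - T37_K * ds_salt / 1000.0, mode="nn"
    )


def lna_tm(seq: str, mask: LnaMask, cond: HybridizationConditions | None = None,
           mode: str = "approximate", params: ThermoParams | None = None) -> ThermoResult:
    """Tm of an LNA-modified backbone.

    approximate: NN Tm plus the configured per-base increment for each modified
    position (order-independent, non-decreasing in mask size). refined: NN
    computation with LNA-perturbed stack parameters where available, additive
    fallback otherwise; the result's ``mode`` records which path was taken.
    """
    cond = cond or HybridizationConditions()
    params = params or load_thermo_params()
    s = _check_dna(seq, "lna_tm")
    mask.validate_bounds(len(s))
    if mode not in ("approximate", "refined"):
        raise ParameterError(f"mode must be 'approximate' or 'refined', got {mode!r}")
    if not mask.positions:
        base = nn_thermo(s, cond, params)
        return ThermoResult(base.tm_C, base.dH, base.dS, base.dG37, mode="nn")
    if mode == "approximate":
        base = nn_thermo(s, cond, params)
        bump = sum(params.lna_increments[s[p]] for p in mask.positions)
        return ThermoResult(base.tm_C + bump, base.dH, base.dS, base.dG37,
                            mode="approximate")
    dh, ds, fallback = _nn_sums(s, params, mask.positions)
    tm_C, ds_salt = _tm_from_sums(dh, ds, s, cond, params)
    tm_C += sum(params.lna_increments[s[p]] for p in fallback)
    label = "refined+approximate" if fallback else "refined"
    return ThermoResult(tm_C, dh, ds_salt, dh - T37_K * ds_salt / 1000.0, mode=label)


def _complementary(a: str, b: str) -> bool:
    return _DNA_COMP[a] == b


def _score_runs(pair_flags, stack_at) -> tuple:
    """Sum stack dG37 over maximal True-runs of length >= 2.

    ``pair_flags[k]`` marks a Watson-Crick pair at ladder position k;
    ``stack_at(k)`` gives the stack dG37 between ladder positions k and k+1.
    Returns (dG, runs) with runs as (start, length) tuples.
    """
    dg = 0.0
    runs = []
    k = 0
    n = len(pair_flags)
    while k < n:
        if not pair_flags[k]:
            k += 1
            continue
        j = k
        while j + 1 < n and pair_flags[j + 1]:
            j += 1
        if j > k:
            runs.append((k, j - k + 1))
            for t in range(k, j):
                dg += stack_at(t)
        k = j + 1
    return dg, tuple(runs)


def self_dimer(seq: str, params: ThermoParams | None = None) -> DuplexStructure:
    """Most stable ungapped antiparallel self-alignment (homodimer screen).

    Every alignment shift of the sequence against a second copy of itself is
    scanned; complementary runs of >= 2 bp are scored by their NN stack dG37
    sum and all runs in a shift contribute. The minimum (most negative) total
    is returned; 0 when no pairing exists.
    """
    params = params or load_thermo_params()
    s = _check_dna(seq, "self_dimer")
    if len(s) < 4:
        raise SequenceTooShortError(f"self_dimer requires length >= 4, got {len(s)}")
    n = len(s)
    best = DuplexStructure()
    for shift in range(2 * n - 1):  # strand1 index i pairs strand2 index shift - i
        lo = max(0, shift - n + 1)
        hi = min(n - 1, shift)
        idx = range(lo, hi + 1)
        flags = [_complementary(s[i], s[shift - i]) for i in idx]
        dg, runs = _score_runs(flags, lambda k: params.stack_dg37(s[lo + k : lo + k + 2]))
        runs = tuple((lo + st, ln) for st, ln in runs)
        offset = shift - (n - 1)
        if dg < best.dG - 1e-12 or (
            abs(dg - best.dG) <= 1e-12 and dg < 0
            and (abs(offset), offset) < (abs(best.offset), best.offset)
        ):
            best = DuplexStructure(offset=offset, paired_runs=runs, dG=dg)
    return best if best.dG < 0 else DuplexStructure()


def hairpin(seq: str, min_loop: int = 3, params: ThermoParams | None = None) -> DuplexStructure:
    """Best single stem-loop: stack-sum dG37 of the stem plus a flat loop penalty.

    All placements with stem length >= 2 and loop >= ``min_loop`` are scanned.
    Returns dG = 0 when no stem scores below zero (including sequences too
    short to fold).
    """
    params = params or load_thermo_params()
    s = _check_dna(seq, "hairpin")
    n = len(s)
    best = DuplexStructure()
    penalty = params.hairpin_loop_penalty
    for i in range(n - 3):  # 5' arm start
        for j in range(i + 2 + min_loop, n - 1):  # 3' arm start
            # stems anchored at (i, j): s[i+k] pairs s[j + L - 1 - k],
            # loop = j - (i + L) >= min_loop and the 3' arm must fit.
            max_len = min(j - i - min_loop, n - j)
            for L in range(2, max_len + 1):
                ok = all(_complementary(s[i + k], s[j + L - 1 - k]) for k in range(L))
                if not ok:
                    continue
                stack_sum = sum(params.stack_dg37(s[i + k : i + k + 2]) for k in range(L - 1))
                total = stack_sum + penalty
                if total < best.dG - 1e-12:
                    best = DuplexStructure(offset=j, paired_runs=((i, L),), dG=total)
    return best if best.dG < 0 else DuplexStructure()
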