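"""Design of LNA/docking-strand hybrid probes for PAINT imaging of small RNAs.

The pipeline mirrors how such probes are designed in practice:

1. reverse-complement the 21-24 nt target RNA;
2. enumerate every contiguous 19-22 nt window and keep those whose DNA-only
   NN Tm is under a ceiling (60 deg C), preferring the longest window with the
   lowest Tm; the top-ranked window becomes the probe backbone;
3. exhaustively place ``n_lna`` locked bases on the backbone, rejecting masks
   with a run of more than four consecutive LNAs or three or more consecutive
   LNA-modified G/C bases (which over-stabilize);
4. shortlist the 200 placements with the highest approximate (additive) LNA Tm;
5. append the linker (default ``tattcgt``) and a docking strand, screen each
   full sequence for self-dimers and hairpins, recompute a refined backbone Tm,
   and report the top 10 surviving candidates per docking strand.

Deterministic throughout: ties break on backbone start, then mask order, so a
rerun yields a byte-identical order sheet.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .config import ThermoParams, get_docking_sequence, load_docking_library, load_thermo_params
from .errors import NoCandidatesError, ParameterError, SequenceTooShortError
from .thermo import (
    HybridizationConditions,
    LnaMask,
    hairpin,
    lna_tm,
    nn_thermo,
    reverse_complement,
    self_dimer,
)

__all__ = [
    "BackboneCandidate",
    "DockingStrand",
    "DesignedProbe",
    "DesignResult",
    "select_backbones",
    "enumerate_lna_masks",
    "validate_lna_mask",
    "shortlist",
    "assemble_probe",
    "screen_probe",
    "design",
    "write_order_sheet",
]

DEFAULT_LINKER = "tattcgt"
BACKBONE_LENGTHS = (19, 22)
TM_CEILING_C = 60.0
LNA_COUNT_RANGE = (5, 9)
MAX_LNA_RUN = 4
MAX_GC_LNA_RUN = 2  # a run of 3+ consecutive LNA G/C bases is rejected
DIMER_DG_FLOOR = -9.0  # kcal/mol; more negative -> rejected
HAIRPIN_DG_FLOOR = -3.0


@dataclass(frozen=True)
class BackboneCandidate:
    """A 19-22 nt window of the reverse-complemented target."""

    sequence: str
    start: int
    tm_C: float
    under_ceiling: bool


@dataclass(frozen=True)
class DockingStrand:
    """Named docking sequence; the imager strand is its reverse complement."""

    id: str
    sequence: str
    imager: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "imager", reverse_complement(self.sequence, "DNA"))


@dataclass(frozen=True)
class DesignedProbe:
    """A fully assembled probe: backbone (+LNA mask) + linker + docking strand."""

    backbone: BackboneCandidate
    lna: LnaMask
    linker: str
    docking: DockingStrand
    full_sequence: str
    tm_approx_C: float
    tm_refined_C: float = float("nan")
    dimer_dG: float = float("nan")
    hairpin_dG: float = float("nan")
    rank: int = 0

    @property
    def imager(self) -> str:
        return self.docking.imager

    def display_sequence(self) -> str:
        """Full sequence with each LNA base written as ``+N`` (backbone upper,
        linker lower, docking upper)."""
        marked = []
        lna = set(self.lna.positions)
        for i, c in enumerate(self.backbone.sequence):
            marked.append(("+" + c) if i in lna else c)
        return "".join(marked) + self.linker.lower() + self.docking.sequence


@dataclass
class DesignResult:
    """Per-docking-strand ranked probes plus pipeline warnings."""

    probes: dict
    backbone: BackboneCandidate
    warnings: list = field(default_factory=list)


def select_backbones(target: str, cond: HybridizationConditions | None = None,
                     tm_ceiling_C: float = TM_CEILING_C,
                     lengths: tuple = BACKBONE_LENGTHS,
                     params: ThermoParams | None = None) -> list:
    """Enumerate and rank candidate backbone windows.

    Every contiguous window of each length in ``lengths[0]..lengths[1]`` of the
    reverse-complemented target is scored by DNA-only NN Tm and flagged when
    under the ceiling. Sorted longest-first, then lowest Tm, then start. When
    no window is under the ceiling all windows are returned with
    ``under_ceiling=False`` and the caller may fall back to the minimum-Tm one.
    """
    cond = cond or HybridizationConditions()
    params = params or load_thermo_params()
    lo, hi = lengths
    rc = reverse_complement(target).upper()
    if len(rc) < lo:
        raise SequenceTooShortError(
            f"target length {len(rc)} is below the minimum backbone length {lo}"
        )
    cands = []
    for length in range(lo, min(hi, len(rc)) + 1):
        for start in range(len(rc) - length + 1):
            window = rc[start : start + length]
            tm = nn_thermo(window, cond, params).tm_C
            cands.append(BackboneCandidate(window, start, tm, tm < tm_ceiling_C))
    if not any(c.under_ceiling for c in cands):
        cands = [replace(c, under_ceiling=False) for c in cands]
    cands.sort(key=lambda c: (-len(c.sequence), c.tm_C, c.start))
    return cands


def validate_lna_mask(backbone: str, mask: LnaMask,
                      n_range: tuple = LNA_COUNT_RANGE) -> tuple:
    """Check an LNA placement against count, run-length and G/C-run rules.

    Returns ``(ok, reason)`` where ``reason`` names the violated rule and its
    location (None when valid).
    """
    mask.validate_bounds(len(backbone))
    pos = mask.positions
    if not (n_range[0] <= len(pos) <= n_range[1]):
        return False, f"count rule: {len(pos)} LNAs outside [{n_range[0]}, {n_range[1]}]"
    seq = backbone.upper()
    run_start = 0
    for k in range(1, len(pos) + 1):
        if k == len(pos) or pos[k] != pos[k - 1] + 1:
            run = pos[run_start:k]
            if len(run) > MAX_LNA_RUN:
                return False, f"run rule: {len(run)} consecutive LNAs at {run[0]}-{run[-1]}"
            gc_run = 0
            for p in run:
                if seq[p] in "GC":
                    gc_run += 1
                    if gc_run > MAX_GC_LNA_RUN:
                        return False, (
                            f"G/C rule: {gc_run} consecutive LNA G/C bases "
                            f"ending at position {p}"
                        )
                else:
                    gc_run = 0
            run_start = k
    return True, None


def enumerate_lna_masks(backbone: str, sizes=None, n_range: tuple = LNA_COUNT_RANGE):
    """Yield every valid LNA mask of each requested size, lexicographically.

    ``sizes`` defaults to the full allowed range. A generator: the raw subset
    count (sum of binomials) reaches ~10^6 for a 22-mer, so masks are streamed
    rather than materialized.
    """
    if sizes is None:
        sizes = range(n_range[0], n_range[1] + 1)
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 1 or sizes[-1] > len(backbone):
        raise ParameterError(
            f"LNA sizes {sizes} outside [1, {len(backbone)}] for this backbone"
        )
    for k in sizes:
        for combo in itertools.combinations(range(len(backbone)), k):
            mask = LnaMask(combo)
            ok, _ = validate_lna_mask(backbone, mask, (min(sizes), max(sizes)))
            if ok:
                yield mask


def shortlist(backbone_masks, cond: HybridizationConditions | None = None,
              k: int = 200, params: ThermoParams | None = None) -> list:
    """Top ``k`` (backbone, mask) pairs by approximate LNA Tm from a stream.

    Ties break deterministically: earlier backbone start, then lexicographically
    smaller mask. Returns ``[(BackboneCandidate, LnaMask, tm_approx), ...]``
    sorted best-first.
    """
    cond = cond or HybridizationConditions()
    params = params or load_thermo_params()
    heap = []  # min-heap of sort keys; larger key = better candidate
    counter = itertools.count()
    empty = True
    for bb, mask in backbone_masks:
        empty = False
        bump = sum(params.lna_increments[bb.sequence[p]] for p in mask.positions)
        tm = bb.tm_C + bump
        key = (tm, -bb.start, tuple(-p for p in mask.positions))
        item = (key, next(counter), bb, mask, tm)
        if len(heap) < k:
            heapq.heappush(heap, item)
        elif key > heap[0][0]:
            heapq.heapreplace(heap, item)
    if empty:
        raise NoCandidatesError("shortlist received an empty candidate stream")
    ranked = sorted(heap, key=lambda it: it[0], reverse=True)
    return [(bb, mask, tm) for _, _, bb, mask, tm in ranked]


def assemble_probe(backbone: BackboneCandidate, mask: LnaMask,
                   linker: str = DEFAULT_LINKER,
                   docking: DockingStrand | None = None,
                   tm_approx_C: float | None = None,
                   params: ThermoParams | None = None) -> DesignedProbe:
    """Concatenate backbone -> linker -> docking strand (5'->3')."""
    if docking is None:
        raise ParameterError("assemble_probe requires a DockingStrand")
    if not linker:
        raise ParameterError("linker must be non-empty")
    from .thermo import _check_dna  # alphabet check only

    _check_dna(linker, "assemble_probe(linker)")
    mask.validate_bounds(len(backbone.sequence))
    params = params or load_thermo_params()
    if tm_approx_C is None:
        tm_approx_C = backbone.tm_C + sum(
            params.lna_increments[backbone.sequence[p]] for p in mask.positions
        )
    full = backbone.sequence.upper() + linker.lower() + docking.sequence.upper()
    return DesignedProbe(
        backbone=backbone, lna=mask, linker=linker.lower(), docking=docking,
        full_sequence=full, tm_approx_C=tm_approx_C,
    )


def screen_probe(probe: DesignedProbe, cond: HybridizationConditions | None = None,
                 params: ThermoParams | None = None) -> DesignedProbe:
    """Fill dimer/hairpin dG (full sequence) and refined Tm (backbone only).

    The docking strand and linker never hybridize the target, so the refined
    Tm is computed on the LNA-modified backbone alone.
    """
    cond = cond or HybridizationConditions()
    params = params or load_thermo_params()
    full = probe.full_sequence.upper()
    dimer = self_dimer(full, params)
    hp = hairpin(full, params=params)
    refined = lna_tm(probe.backbone.sequence, probe.lna, cond, "refined", params)
    return replace(probe, dimer_dG=dimer.dG, hairpin_dG=hp.dG, tm_refined_C=refined.tm_C)


def _vectorized_shortlist(backbone: BackboneCandidate, n_lna: int, k: int,
                          params: ThermoParams) -> list:
    """Numpy path equivalent to enumerate_lna_masks + shortlist for one size.

    Tested against the streamed path; exists because the exhaustive placement
    enumeration (C(22,8) ~ 3.2e5 subsets) dominates design time in pure Python.
    """
    seq = backbone.sequence.upper()
    L = len(seq)
    combos = np.array(list(itertools.combinations(range(L), n_lna)), dtype=np.int16)
    step = np.diff(combos, axis=1) == 1  # consecutive positions
    # run rule: MAX_LNA_RUN consecutive steps => run of MAX_LNA_RUN+1 LNAs
    bad_run = np.zeros(len(combos), dtype=bool)
    for i in range(step.shape[1] - MAX_LNA_RUN + 1):
        bad_run |= step[:, i : i + MAX_LNA_RUN].all(axis=1)
    # G/C rule: MAX_GC_LNA_RUN consecutive steps whose bases are all G/C
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
    gc_at = is_gc[combos]
    gc_step = step & gc_at[:, :-1] & gc_at[:, 1:]
    bad_gc = np.zeros(len(combos), dtype=bool)
    for i in range(gc_step.shape[1] - MAX_GC_LNA_RUN + 1):
        bad_gc |= gc_step[:, i : i + MAX_GC_LNA_RUN].all(axis=1)
    keep = ~(bad_run | bad_gc)
    combos = combos[keep]
    incr = np.array([params.lna_increments[c] for c in seq])
    tms = backbone.tm_C + incr[combos].sum(axis=1)
    # sort by Tm desc, then mask lexicographic asc (backbone start is constant)
    order = np.lexsort(tuple(combos[:, j] for j in range(n_lna - 1, -1, -1)) + (-tms,))
    top = order[:k]
    return [(backbone, LnaMask(tuple(int(p) for p in combos[i])), float(tms[i]))
            for i in top]


def design(target: str, cond: HybridizationConditions | None = None,
           docking_ids=("P0",), top_n: int = 10, n_lna: int = 8,
           k_shortlist: int = 200, linker: str = DEFAULT_LINKER,
           tm_ceiling_C: float = TM_CEILING_C, lengths: tuple = BACKBONE_LENGTHS,
           dimer_dg_floor: float = DIMER_DG_FLOOR,
           hairpin_dg_floor: float = HAIRPIN_DG_FLOOR,
           docking_library: dict | None = None,
           params: ThermoParams | None = None) -> DesignResult:
    """Full probe-design pipeline for one target small RNA.

    Returns ranked probes per docking strand. Candidates whose full sequence
    self-dimer or hairpin dG falls below the configured floors are dropped;
    survivors are ordered by refined backbone Tm (descending) with
    deterministic tie-breaks, and the first ``top_n`` get ranks 1..n.
    """
    cond = cond or HybridizationConditions()
    params = params or load_thermo_params()
    library = docking_library if docking_library is not None else load_docking_library()
    warnings = []

    backbones = select_backbones(target, cond, tm_ceiling_C, lengths, params)
    chosen = next((b for b in backbones if b.under_ceiling), None)
    if chosen is None:
        chosen = min(backbones, key=lambda b: (b.tm_C, -len(b.sequence), b.start))
        warnings.append(
            f"no backbone window under the {tm_ceiling_C} C ceiling; proceeding "
            f"with the minimum-Tm window (Tm {chosen.tm_C:.2f} C)"
        )
    if not (1 <= n_lna <= len(chosen.sequence)):
        raise ParameterError(f"n_lna {n_lna} invalid for backbone length {len(chosen.sequence)}")

    short = _vectorized_shortlist(chosen, n_lna, k_shortlist, params)
    if not short:
        raise NoCandidatesError("no LNA placement satisfies the run constraints")

    # refined Tm is docking-independent; order candidates once
    refined = {}
    for bb, mask, tm_a in short:
        refined[mask.positions] = lna_tm(bb.sequence, mask, cond, "refined", params).tm_C
    ordered = sorted(short, key=lambda it: (-refined[it[1].positions], it[0].start,
                                            it[1].positions))

    results = {}
    for did in docking_ids:
        docking = DockingStrand(did, get_docking_sequence(library, did))
        kept = []
        for bb, mask, tm_a in ordered:
            probe = assemble_probe(bb, mask, linker, docking, tm_a, params)
            probe = screen_probe(probe, cond, params)
            if probe.dimer_dG < dimer_dg_floor or probe.hairpin_dG < hairpin_dg_floor:
                continue
            kept.append(probe)
            if len(kept) == top_n:
                break
        if not kept:
            warnings.append(
                f"docking {did}: no candidate passed the dimer/hairpin screens"
            )
        results[did] = [replace(p, rank=i + 1) for i, p in enumerate(kept)]
    return DesignResult(probes=results, backbone=chosen, warnings=warnings)


ORDER_SHEET_COLUMNS = [
    "target_id", "docking_id", "rank", "full_sequence", "backbone",
    "lna_positions", "tm_approx_C", "tm_refined_C", "dimer_dG", "hairpin_dG",
    "imager_sequence",
]


def write_order_sheet(result: DesignResult, target_id: str, path) -> None:
    """Write the ranked probes of one design run as a TSV order sheet."""
    with open(path, "w") as fh:
        fh.write("\t".join(ORDER_SHEET_COLUMNS) + "\n")
        for did in result.probes:
            for p in result.probes[did]:
                fh.write("\t".join([
                    target_id, did, str(p.rank), p.display_sequence(),
                    p.backbone.sequence,
                    ",".join(str(i) for i in p.lna.positions),
                    f"{p.tm_approx_C:.2f}", f"{p.tm_refined_C:.2f}",
                    f"{p.dimer_dG:.2f}", f"{p.hairpin_dG:.2f}",
                    p.imager,
                ]) + "\n")
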