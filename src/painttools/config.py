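"""Loading of thermodynamic parameter tables and the docking-strand library.

All numeric tables live in YAML so that users can swap in their own nearest-
neighbor set, LNA increments or docking strands without touching code. The
defaults ship inside the package (``painttools/data``). The default docking
library is synthetic (see ``docking_strands_synthetic.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .errors import ParameterError, UnknownDockingError

__all__ = ["ThermoParams", "load_thermo_params", "load_docking_library"]

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _revcomp_dna(s: str) -> str:
    return "".join(_WC[c] for c in reversed(s))


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor parameter set plus LNA and hairpin configuration.

    ``stacks`` is expanded to all 16 dinucleotides (reverse-complement
    symmetric); values are ``(dH kcal/mol, dS cal/(mol K))`` tuples.
    """

    stacks: dict = field(repr=False)
    init_per_duplex: tuple
    init_terminal_AT: tuple
    init_terminal_GC: tuple
    init_symmetry: tuple
    salt_entropy_coefficient: float
    mg_equivalent_coefficient: float
    lna_increments: dict
    lna_stacks: dict
    hairpin_loop_penalty: float

    def stack_dg37(self, dinuc: str) -> float:
        """Stack free energy at 37 deg C (kcal/mol) for a 5'->3' dinucleotide."""
        dh, ds = self.stacks[dinuc]
        return dh - 310.15 * ds / 1000.0


def _expand_stacks(raw: dict) -> dict:
    out = {}
    for key, v in raw.items():
        pair = (float(v["dH"]), float(v["dS"]))
        out[key] = pair
        out.setdefault(_revcomp_dna(key), pair)
    missing = {a + b for a in "ACGT" for b in "ACGT"} - set(out)
    if missing:
        raise ParameterError(f"NN stack table incomplete; missing {sorted(missing)}")
    return out


def _load_thermo_dict(data: dict) -> ThermoParams:
    init = data["initiation"]
    incr = {k: float(v) for k, v in data["lna_increments"].items()}
    for base, val in incr.items():
        if val < 0:
            raise ParameterError(
                f"LNA increment for {base} is negative ({val}); increments must be >= 0"
            )
    return ThermoParams(
        stacks=_expand_stacks(data["stacks"]),
        init_per_duplex=(float(init["per_duplex"]["dH"]), float(init["per_duplex"]["dS"])),
        init_terminal_AT=(float(init["terminal_AT"]["dH"]), float(init["terminal_AT"]["dS"])),
        init_terminal_GC=(float(init["terminal_GC"]["dH"]), float(init["terminal_GC"]["dS"])),
        init_symmetry=(float(init["symmetry"]["dH"]), float(init["symmetry"]["dS"])),
        salt_entropy_coefficient=float(data["salt"]["entropy_coefficient"]),
        mg_equivalent_coefficient=float(data["salt"]["mg_equivalent_coefficient"]),
        lna_increments=incr,
        lna_stacks={
            k: (float(v["ddH"]), float(v["ddS"])) for k, v in data.get("lna_stacks", {}).items()
        },
        hairpin_loop_penalty=float(data.get("hairpin_loop_penalty", 3.0)),
    )


@lru_cache(maxsize=None)
def _default_thermo_params() -> ThermoParams:
    text = resources.files("painttools.data").joinpath("nn_dna.yaml").read_text()
    return _load_thermo_dict(yaml.safe_load(text))


def load_thermo_params(path: str | Path | None = None) -> ThermoParams:
    """Load a thermodynamic parameter set (package default when ``path`` is None)."""
    if path is None:
        return _default_thermo_params()
    with open(path) as fh:
        return _load_thermo_dict(yaml.safe_load(fh))


def load_docking_library(path: str | Path | None = None) -> dict:
    """Return ``{id: sequence}`` for the docking-strand library.

    The packaged default is a synthetic orthogonal P-series stand-in; pass a
    YAML file of ``id: sequence`` pairs to use real, published strands.
    """
    if path is None:
        text = resources.files("painttools.data").joinpath(
            "docking_strands_synthetic.yaml"
        ).read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ParameterError("docking library must be a non-empty mapping of id -> sequence")
    return {str(k): str(v).upper() for k, v in raw.items()}


def get_docking_sequence(library: dict, docking_id: str) -> str:
    if docking_id not in library:
        raise UnknownDockingError(
            f"docking id {docking_id!r} not in library {sorted(library)}"
        )
    return library[docking_id]
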