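"""Flat key/value run configuration for the design pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .clusters import DEFAULT_CC_LOOP, DEFAULT_PROXIMITY_CUTOFF
from .errors import ConfigurationError
from .imgt import RegionScheme
from .variants import DEFAULT_LINKER, DEFAULT_TAG


@dataclass
class RunConfig:
    """Everything the design pipeline can be steered with.

    Stored as a flat, auditable key=value text file; unknown keys are
    rejected on load.
    """

    max_fr1_mismatches: int = 4
    vh_required_residues: str = "103:Y,42:V"
    vl_required_residues: str = "103:Y"
    cc_loop: str = f"{DEFAULT_CC_LOOP[0]}-{DEFAULT_CC_LOOP[1]}"
    proximity_cutoff: float = DEFAULT_PROXIMITY_CUTOFF
    linker: str = DEFAULT_LINKER
    tag: str = DEFAULT_TAG
    variant_prefix: str = "S1"
    vh_v_gene: str = ""  # override the top-ranked V donor by label, e.g. IGHVS1-1*01
    vh_j_gene: str = ""
    vl_v_gene: str = ""
    vl_j_gene: str = ""
    cluster_i_positions: str = ""  # comma-separated VH IMGT positions (no-structure mode)
    seed: int = 0
    output_dir: str = "frshift-out"
    scheme: RegionScheme = field(default_factory=RegionScheme, repr=False)

    # -- derived accessors -------------------------------------------------

    def cc_loop_interval(self):
        lo, _, hi = self.cc_loop.partition("-")
        return int(lo), int(hi)

    def required_residues(self, chain_kind: str):
        raw = self.vh_required_residues if chain_kind == "VH" else self.vl_required_residues
        pairs = []
        for item in filter(None, (s.strip() for s in raw.split(","))):
            pos, _, aa = item.partition(":")
            pairs.append((int(pos), aa.strip()))
        return tuple(pairs)

    def cluster_i_position_set(self):
        if not self.cluster_i_positions.strip():
            return None
        return {int(p) for p in self.cluster_i_positions.split(",")}

    # -- (de)serialization -------------------------------------------------

    _SCALAR_FIELDS = (
        "max_fr1_mismatches", "vh_required_residues", "vl_required_residues",
        "cc_loop", "proximity_cutoff", "linker", "tag", "variant_prefix",
        "vh_v_gene", "vh_j_gene", "vl_v_gene", "vl_j_gene",
        "cluster_i_positions", "seed", "output_dir",
    )

    def to_text(self) -> str:
        lines = [f"{name} = {getattr(self, name)}" for name in self._SCALAR_FIELDS]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, sep, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not sep or key not in cls._SCALAR_FIELDS:
                raise ConfigurationError(f"unknown or malformed config line {raw!r}")
            if types[key] == "int":
                kwargs[key] = int(value)
            elif types[key] == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_text(fh.read())
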