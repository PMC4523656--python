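"""Low-frequency tissue conductivities and label-to-sigma assignment.

The package ships a versioned table of quasi-static electrical conductivities
(S/m) for the tissues of a whole-body human model, plus the two electrode
materials (a metal-like rectangular pad and a saline-soaked sponge).  Grouped
tissues that share one literature value are stored as one canonical label with
aliases, so lookups work both ways (``"skull"`` resolves to the bone entry,
``"csf"`` to cerebrospinal fluid).  The shipped skin value already folds the
subcutaneous adipose layer into a single effective conductivity; it is used
as-is and never re-derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .volumes import LabelVolume, ScalarVolume

__all__ = ["ConductivityTable", "default_conductivity_table", "assign_conductivity"]


@dataclass
class ConductivityTable:
    """Map from tissue label (canonical or alias) to conductivity in S/m."""

    sigma: dict[str, float]            # canonical -> S/m
    aliases: dict[str, str] = field(default_factory=dict)  # alias -> canonical
    version: str = "1.0"

    def __post_init__(self):
        for name, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"negative conductivity for {name!r}: {s}")
        for a, c in self.aliases.items():
            if c not in self.sigma:
                raise ValueError(f"alias {a!r} points to unknown canonical label {c!r}")

    def canonical(self, name: str) -> str:
        if name in self.sigma:
            return name
        if name in self.aliases:
            return self.aliases[name]
        raise KeyError(f"tissue {name!r} not in conductivity table")

    def lookup(self, name: str) -> float:
        """Conductivity in S/m for a canonical label or any alias."""
        return self.sigma[self.canonical(name)]

    def __contains__(self, name: str) -> bool:
        return name in self.sigma or name in self.aliases

    # ---------------------------------------------------------------- I/O
    def to_json(self, path: str | Path) -> None:
        entries = []
        rev: dict[str, list[str]] = {c: [] for c in self.sigma}
        for a, c in self.aliases.items():
            rev[c].append(a)
        for c, s in self.sigma.items():
            entries.append({"canonical_label": c, "aliases": sorted(rev[c]), "sigma_S_per_m": s})
        Path(path).write_text(json.dumps({"version": self.version, "units": "S/m", "entries": entries}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConductivityTable":
        return cls._from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def _from_dict(cls, d: dict) -> "ConductivityTable":
        sigma, aliases = {}, {}
        for e in d["entries"]:
            sigma[e["canonical_label"]] = float(e["sigma_S_per_m"])
            for a in e.get("aliases", []):
                aliases[a] = e["canonical_label"]
        return cls(sigma, aliases, d.get("version", "1.0"))


def default_conductivity_table() -> ConductivityTable:
    """The built-in conductivity table (every tissue row plus pad/sponge/air)."""
    text = resources.files("tdcsim.data").joinpath("conductivity_table.json").read_text()
    return ConductivityTable._from_dict(json.loads(text))


def assign_conductivity(labels: LabelVolume, table: ConductivityTable | None = None) -> ScalarVolume:
    """Per-voxel conductivity volume from a label volume.

    Every label id present in the volume must name a tissue known to the
    table; air voxels get sigma = 0 exactly.
    """
    if table is None:
        table = default_conductivity_table()
    present = labels.present_ids()
    lut = np.zeros(int(present.max()) + 1 if len(present) else 1, dtype=np.float64)
    for i in present:
        i = int(i)
        name = labels.names.get(i)
        if name is None:
            raise KeyError(
                f"label id {i} ({int(np.sum(labels.labels == i))} voxels) has no name in this volume"
            )
        try:
            lut[i] = table.lookup(name)
        except KeyError:
            raise KeyError(
                f"label id {i} ({name!r}, {int(np.sum(labels.labels == i))} voxels) "
                "has no conductivity table entry"
            ) from None
    return ScalarVolume(labels.grid, lut[labels.labels], units="S/m")
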