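"""In-memory benchmark container: per-target actives/decoys with profiles.

A benchmark is the unit every screening route consumes: a list of targets,
each carrying a template-derived :class:`~fragscreen.pockets.TargetProfile`
plus labeled ligand lists, and a pairwise target sequence-identity matrix
used for leave-one-target-out exclusion. On-disk reading/writing of this
layout lives in :mod:`fragscreen.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chem import SmilesRecord
from .pockets import TargetProfile, TemplatePocketRecord


@dataclass
class BenchmarkTarget:
    profile: TargetProfile
    actives: list[SmilesRecord]
    decoys: list[SmilesRecord]
    #: All candidate pockets before filtering (kept for auditability).
    candidates: list[TemplatePocketRecord] = field(default_factory=list)
    family: int | None = None

    @property
    def target_id(self) -> str:
        return self.profile.target_id

    def library(self) -> list[SmilesRecord]:
        """The full screening library: actives and decoys pooled."""
        return list(self.actives) + list(self.decoys)

    def labels(self) -> dict[str, int]:
        out = {rec.mol_id: 1 for rec in self.actives}
        out.update({rec.mol_id: 0 for rec in self.decoys})
        return out


@dataclass
class Benchmark:
    targets: list[BenchmarkTarget]
    #: Symmetric pairwise sequence-identity matrix (unit diagonal),
    #: indexed by target id on both axes.
    identity: pd.DataFrame
    spec: dict | None = None

    def __post_init__(self) -> None:
        ids = self.target_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate target ids in benchmark")
        missing = set(ids) - set(self.identity.index)
        if missing:
            raise ValueError(f"identity matrix missing targets: {sorted(missing)}")

    @property
    def target_ids(self) -> list[str]:
        return [t.target_id for t in self.targets]

    def __getitem__(self, target_id: str) -> BenchmarkTarget:
        for t in self.targets:
            if t.target_id == target_id:
                return t
        raise KeyError(target_id)

    def __len__(self) -> int:
        return len(self.targets)
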