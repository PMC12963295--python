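"""Genotype roles and pedigree validation.

A panel mixes three genotype roles: doubled-haploid parent lines (fully
homozygous, no pedigree), program hybrids (each the F1 of two named lines),
and commercial check hybrids (no pedigree available). Heterosis and
parent-hybrid prediction only apply to program hybrids; profiling and
clustering use every genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd


class Role(str, Enum):
    LINE = "LINE"
    HYBRID = "HYBRID"
    COMMERCIAL_HYBRID = "COMMERCIAL_HYBRID"


@dataclass(frozen=True)
class Genotype:
    genotype_id: str
    role: Role
    mother_id: str | None = None
    father_id: str | None = None


class Pedigree:
    """Validated collection of genotypes with parent links.

    Raises ``ValueError`` at construction if a hybrid lacks a parent, a
    parent is not a registered LINE, or a non-hybrid carries parent IDs.
    """

    def __init__(self, genotypes: Iterable[Genotype]):
        self.genotypes: dict[str, Genotype] = {}
        for g in genotypes:
            if g.genotype_id in self.genotypes:
                raise ValueError(f"duplicate genotype_id: {g.genotype_id}")
            self.genotypes[g.genotype_id] = g
        self._validate()

    def _validate(self) -> None:
        for g in self.genotypes.values():
            if g.role is Role.HYBRID:
                if not g.mother_id or not g.father_id:
                    raise ValueError(f"hybrid {g.genotype_id} is missing a parent id")
                for pid in (g.mother_id, g.father_id):
                    parent = self.genotypes.get(pid)
                    if parent is None:
                        raise ValueError(f"hybrid {g.genotype_id}: unknown parent {pid}")
                    if parent.role is not Role.LINE:
                        raise ValueError(
                            f"hybrid {g.genotype_id}: parent {pid} has role "
                            f"{parent.role.value}, expected LINE"
                        )
            else:
                if g.mother_id or g.father_id:
                    raise ValueError(
                        f"{g.role.value} {g.genotype_id} must not carry parent ids"
                    )

    def __len__(self) -> int:
        return len(self.genotypes)

    def __contains__(self, genotype_id: str) -> bool:
        return genotype_id in self.genotypes

    def __getitem__(self, genotype_id: str) -> Genotype:
        return self.genotypes[genotype_id]

    @property
    def lines(self) -> list[Genotype]:
        return [g for g in self.genotypes.values() if g.role is Role.LINE]

    @property
    def hybrids(self) -> list[Genotype]:
        """Program hybrids with known parents (commercial checks excluded)."""
        return [g for g in self.genotypes.values() if g.role is Role.HYBRID]

    @property
    def commercial_hybrids(self) -> list[Genotype]:
        return [g for g in self.genotypes.values() if g.role is Role.COMMERCIAL_HYBRID]

    def parents_of(self, hybrid_id: str) -> tuple[str, str]:
        g = self.genotypes[hybrid_id]
        if g.role is not Role.HYBRID:
            raise ValueError(f"{hybrid_id} is not a program hybrid")
        assert g.mother_id is not None and g.father_id is not None
        return g.mother_id, g.father_id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype_id": [g.genotype_id for g in self.genotypes.values()],
                "role": [g.role.value for g in self.genotypes.values()],
                "mother_id": [g.mother_id or "" for g in self.genotypes.values()],
                "father_id": [g.father_id or "" for g in self.genotypes.values()],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        def _opt(v) -> str | None:
            if v is None or (isinstance(v, float) and pd.isna(v)) or str(v) == "":
                return None
            return str(v)

        return cls(
            Genotype(
                genotype_id=str(r["genotype_id"]),
                role=Role(r["role"]),
                mother_id=_opt(r.get("mother_id")),
                father_id=_opt(r.get("father_id")),
            )
            for _, r in df.iterrows()
        )
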