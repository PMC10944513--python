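"""Parent-resolved read-count container shared by assignment and dynamics."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ORIGINS = ("maternal", "paternal")


def maternal_species(cross: str) -> str:
    """Which parental species is the mother in the given cross direction."""
    if cross == "forward":
        return "A"
    if cross == "reverse":
        return "B"
    raise ValueError(f"unknown cross label {cross!r}")


def paternal_species(cross: str) -> str:
    return "B" if maternal_species(cross) == "A" else "A"


def origin_to_species(origin: str, cross: str) -> str:
    if origin == "maternal":
        return maternal_species(cross)
    if origin == "paternal":
        return paternal_species(cross)
    raise ValueError(f"unknown origin {origin!r}")


@dataclass
class ParentCountMatrix:
    """Per-gene maternal/paternal read counts across stages for one cross.

    ``data`` is a long-form frame with columns pair_id, stage, maternal,
    paternal (counts of unambiguously assigned reads); ambiguous reads are
    tallied per stage separately and never enter per-gene counts.
    """

    cross: str
    data: pd.DataFrame
    ambiguous: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"pair_id", "stage", "maternal", "paternal"}
        if missing := required - set(self.data.columns):
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.data[["maternal", "paternal"]].to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.data["stage"]))

    def stage_totals(self) -> pd.DataFrame:
        """Total unambiguous maternal/paternal counts per stage."""
        return self.data.groupby("stage", sort=False)[["maternal", "paternal"]].sum()

    @staticmethod
    def concat(slices: list["ParentCountMatrix"]) -> "ParentCountMatrix":
        if not slices:
            raise ValueError("nothing to concatenate")
        cross = slices[0].cross
        if any(s.cross != cross for s in slices):
            raise ValueError("cross labels differ between slices")
        ambiguous: dict[str, int] = {}
        for s in slices:
            for stage, n in s.ambiguous.items():
                ambiguous[stage] = ambiguous.get(stage, 0) + n
        data = pd.concat([s.data for s in slices], ignore_index=True)
        return ParentCountMatrix(cross, data, ambiguous)
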