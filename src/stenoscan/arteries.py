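"""The eleven target intracranial arteries and their binary stenosis labels.

The unit of ground truth and of prediction throughout the package is an
11-element binary vector: one indicator per artery, 1 meaning >=50% diameter
stenosis under the NASCET measurement convention. Ten arteries come in
left/right pairs; the basilar artery (BA) is unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["ArteryId", "ARTERY_ORDER", "LabelVector"]


class ArteryId(str, Enum):
    """Identifier codes for the 11 target arteries.

    Naming: L/R prefix for side, then IICA (intracranial internal carotid),
    ACA (anterior cerebral), MCA (middle cerebral), PCA (posterior cerebral),
    IVA (intracranial vertebral); BA is the basilar artery.
    """

    RIICA = "RIICA"
    RACA = "RACA"
    RMCA = "RMCA"
    RPCA = "RPCA"
    RIVA = "RIVA"
    BA = "BA"
    LIICA = "LIICA"
    LACA = "LACA"
    LMCA = "LMCA"
    LPCA = "LPCA"
    LIVA = "LIVA"

    @property
    def side(self) -> str | None:
        """'left', 'right', or None for the unpaired basilar artery."""
        if self is ArteryId.BA:
            return None
        return "right" if self.value.startswith("R") else "left"

    @property
    def twin(self) -> "ArteryId | None":
        """The contralateral artery, or None for BA."""
        if self is ArteryId.BA:
            return None
        other = ("L" if self.value[0] == "R" else "R") + self.value[1:]
        return ArteryId(other)


#: Canonical reporting order (right-side arteries, BA, then left-side).
ARTERY_ORDER: tuple[ArteryId, ...] = tuple(ArteryId)


@dataclass(frozen=True)
class LabelVector:
    """Binary stenosis indicators for the 11 target arteries.

    ``values[a] == 1`` means artery ``a`` has >=50% diameter stenosis.
    """

    values: dict[ArteryId, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {a: int(self.values.get(a, 0)) for a in ARTERY_ORDER}
        bad = [a for a, v in full.items() if v not in (0, 1)]
        if bad:
            raise ValueError(f"label values must be 0 or 1; bad arteries: {bad}")
        object.__setattr__(self, "values", full)

    def __getitem__(self, artery: ArteryId) -> int:
        return self.values[artery]

    def to_array(self) -> np.ndarray:
        """11-element int array in ``ARTERY_ORDER``."""
        return np.array([self.values[a] for a in ARTERY_ORDER], dtype=np.int64)

    @classmethod
    def from_array(cls, arr) -> "LabelVector":
        arr = np.asarray(arr)
        if arr.shape != (len(ARTERY_ORDER),):
            raise ValueError(f"expected shape (11,), got {arr.shape}")
        return cls({a: int(v) for a, v in zip(ARTERY_ORDER, arr)})

    @classmethod
    def from_positive(cls, positives) -> "LabelVector":
        """Build a vector with the given arteries set to 1."""
        return cls({ArteryId(a): 1 for a in positives})

    def positives(self) -> set[ArteryId]:
        return {a for a, v in self.values.items() if v == 1}

    def any_positive(self) -> int:
        """Binarized with/without-stenosis indicator for the whole report."""
        return int(any(self.values.values()))

    def to_dict(self) -> dict[str, int]:
        return {a.value: v for a, v in self.values.items()}

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "LabelVector":
        return cls({ArteryId(k): int(v) for k, v in d.items()})
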