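"""Shared data model for the paddy-field experiment pipeline.

The experimental unit is a plot sample: one (treatment, depth, replicate)
cell of a randomized-block design with five fertilization treatments in a
rice-eel co-culture system and two sampling depths. The default design is
5 treatments x 2 depths x 3 replicates = 30 samples.

Treatments:
    RT   rice monoculture, 100 % chemical fertilizer (the control)
    IRT  rice-eel co-culture, 100 % chemical fertilizer
    I70  rice-eel co-culture, 70 % chemical fertilizer
    IS   rice-eel co-culture, 70 % chemical + 30 % N from straw
    IO   rice-eel co-culture, 70 % chemical + 30 % N from organic fertilizer
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "Treatment",
    "Depth",
    "PlotSample",
    "SieveFractions",
    "ChemProfile",
    "CopyNumbers",
    "TaxonCountTable",
    "SIEVE_CLASS_BOUNDS_MM",
    "SIEVE_CLASS_COLUMNS",
    "DEFAULT_CLASS_DIAMETERS_MM",
    "CHEM_VARIABLES",
    "COPY_VARIABLES",
]


class Treatment(str, Enum):
    RT = "RT"
    IRT = "IRT"
    I70 = "I70"
    IS = "IS"
    IO = "IO"


class Depth(str, Enum):
    """Sampling depth layer (cm below the surface)."""

    D0_20 = "D0_20"
    D20_40 = "D20_40"


#: Wet-sieving size classes in mm, largest first. The top class is open
#: (everything retained on the 2 mm sieve); the bottom class is the pan.
SIEVE_CLASS_BOUNDS_MM: tuple[tuple[float, float], ...] = (
    (2.0, math.inf),
    (1.0, 2.0),
    (0.5, 1.0),
    (0.25, 0.5),
    (0.053, 0.25),
    (0.0, 0.053),
)

#: Column names of the six class masses in ``sieve.csv``, same order.
SIEVE_CLASS_COLUMNS: tuple[str, ...] = (
    "class_gt2",
    "class_1_2",
    "class_05_1",
    "class_025_05",
    "class_0053_025",
    "class_lt0053",
)

#: Representative diameter X_i per class (mm): the class midpoint, except the
#: open-top >2 mm class which uses its lower bound rather than an invented cap.
DEFAULT_CLASS_DIAMETERS_MM: tuple[float, ...] = (
    2.0,
    1.5,
    0.75,
    0.375,
    0.1515,
    0.0265,
)

CHEM_VARIABLES: tuple[str, ...] = ("SOM", "TN", "TP", "AN", "AP", "pH")
COPY_VARIABLES: tuple[str, ...] = ("bacterial_copies", "fungal_copies")


@dataclass(frozen=True)
class PlotSample:
    """Identity of one field sample."""

    sample_id: str
    treatment: str
    depth: str
    replicate: int
    custom_design: bool = False

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1, "
                f"got {self.replicate}"
            )
        if not self.custom_design:
            if self.treatment not in Treatment._value2member_map_:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown treatment "
                    f"{self.treatment!r} (declare custom_design to allow)"
                )
            if self.depth not in Depth._value2member_map_:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown depth "
                    f"{self.depth!r} (declare custom_design to allow)"
                )


@dataclass(frozen=True)
class SieveFractions:
    """Oven-dry masses retained in the six wet-sieving classes for one sample."""

    sample: PlotSample
    mass_g: tuple[float, ...]
    class_bounds: tuple[tuple[float, float], ...] = SIEVE_CLASS_BOUNDS_MM

    def __post_init__(self) -> None:
        if len(self.mass_g) != len(self.class_bounds):
            raise ValidationError(
                f"sample {self.sample.sample_id!r}: expected "
                f"{len(self.class_bounds)} class masses, got {len(self.mass_g)}"
            )
        for m in self.mass_g:
            if not (m >= 0.0):
                raise ValidationError(
                    f"sample {self.sample.sample_id!r}: negative or non-finite "
                    f"class mass {m}"
                )
        lowers = [b[0] for b in self.class_bounds]
        uppers = [b[1] for b in self.class_bounds]
        if any(lo >= up for lo, up in self.class_bounds):
            raise ValidationError("class intervals must have lower < upper")
        # contiguous, descending: lower bound of class i equals upper of i+1
        for i in range(len(self.class_bounds) - 1):
            if not math.isclose(lowers[i], uppers[i + 1], rel_tol=0, abs_tol=1e-12):
                raise ValidationError(
                    "class intervals must be contiguous and descending"
                )

    @property
    def total_mass_g(self) -> float:
        return float(sum(self.mass_g))


@dataclass(frozen=True)
class ChemProfile:
    """Soil chemistry of one sample.

    Concentration units are dataset metadata (carried alongside, never
    converted); pH is unitless.
    """

    sample: PlotSample
    SOM: float
    TN: float
    TP: float
    AN: float
    AP: float
    pH: float

    def __post_init__(self) -> None:
        for name in ("SOM", "TN", "TP", "AN", "AP"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValidationError(
                    f"sample {self.sample.sample_id!r}: {name} must be "
                    f">= 0, got {v}"
                )
        if not (0.0 <= self.pH <= 14.0):
            raise ValidationError(
                f"sample {self.sample.sample_id!r}: pH must be in [0, 14], "
                f"got {self.pH}"
            )


@dataclass(frozen=True)
class CopyNumbers:
    """qPCR gene-copy abundances (copies per g soil) of one sample."""

    sample: PlotSample
    bacterial_copies: float
    fungal_copies: float

    def __post_init__(self) -> None:
        for name in ("bacterial_copies", "fungal_copies"):
            v = getattr(self, name)
            if not (v > 0.0):
                raise ValidationError(
                    f"sample {self.sample.sample_id!r}: {name} must be "
                    f"> 0, got {v}"
                )


@dataclass
class TaxonCountTable:
    """Samples x taxa non-negative integer counts (OTU/ASV table)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in count table")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon ids in count table")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        empty = np.asarray(self.counts.sum(axis=1) == 0).nonzero()[0]
        if empty.size:
            bad = [self.sample_ids[i] for i in empty]
            raise ValidationError(
                f"samples with no positive counts: {', '.join(bad)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def check_unique_design(samples: Sequence[PlotSample]) -> None:
    """Raise if any (treatment, depth, replicate) triple occurs twice."""
    seen: dict[tuple[str, str, int], str] = {}
    for s in samples:
        key = (s.treatment, s.depth, s.replicate)
        if key in seen:
            raise ValidationError(
                f"duplicate design cell {key}: samples "
                f"{seen[key]!r} and {s.sample_id!r}"
            )
        seen[key] = s.sample_id
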