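"""ddPCR mutation calling for the TERTp C228T and C250T assays.

A droplet digital PCR run partitions the sample into droplets and counts
mutant-positive and total positive (wild-type + mutant) droplets per assay.
The validated calling rule is:

* **mutated** if at least 6 mutant droplets are detected;
* **wildtype** if fewer than 6 mutant droplets with at least 600 total
  positive droplets (which guarantees an analytical sensitivity of 1%,
  6/600);
* **inconclusive** otherwise (too little amplifiable material to call a
  negative).

The positive call does not require the 600-droplet floor: six mutant
droplets are evidence of mutation regardless of how much wild-type
background amplified.  Per-lesion status combines the two assays
disjunctively: any mutated assay makes the lesion mutated; both must be
validly wild-type for a wild-type lesion; a wild-type plus a failed assay
stays inconclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "Assay",
    "Call",
    "DropletCounts",
    "AssayCall",
    "TertpStatus",
    "call_assay",
    "combine_assays",
    "MUTANT_DROPLET_MIN",
    "TOTAL_POSITIVE_MIN",
]

#: Minimum mutant droplets for a positive (mutated) call.
MUTANT_DROPLET_MIN = 6
#: Minimum total positive droplets for a valid negative (wildtype) call.
TOTAL_POSITIVE_MIN = 600


class Assay(str, enum.Enum):
    """The two TERTp hotspot assays."""

    C228T = "C228T"
    C250T = "C250T"


class Call(str, enum.Enum):
    MUTATED = "mutated"
    WILDTYPE = "wildtype"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class DropletCounts:
    """Raw droplet counts for one assay on one lesion."""

    assay: Assay
    mutant_droplets: int
    total_positive_droplets: int

    def __post_init__(self):
        object.__setattr__(self, "assay", Assay(self.assay))
        for name in ("mutant_droplets", "total_positive_droplets"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.mutant_droplets > self.total_positive_droplets:
            raise ValueError(
                f"{self.assay.value}: mutant droplets ({self.mutant_droplets}) exceed "
                f"total positive droplets ({self.total_positive_droplets})"
            )


@dataclass(frozen=True)
class AssayCall:
    assay: Assay
    call: Call

    def __post_init__(self):
        object.__setattr__(self, "assay", Assay(self.assay))
        object.__setattr__(self, "call", Call(self.call))


@dataclass(frozen=True)
class TertpStatus:
    """Per-lesion TERTp status with the detected variant(s) when mutated."""

    status: Call
    detected_variants: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "status", Call(self.status))
        object.__setattr__(
            self, "detected_variants", frozenset(Assay(a) for a in self.detected_variants)
        )
        if (self.status is Call.MUTATED) != bool(self.detected_variants):
            raise ValueError(
                "detected_variants must be non-empty exactly when status is mutated"
            )


def call_assay(counts: DropletCounts) -> AssayCall:
    """Apply the validated calling rule to one assay's droplet counts."""
    if counts.mutant_droplets >= MUTANT_DROPLET_MIN:
        call = Call.MUTATED
    elif counts.total_positive_droplets >= TOTAL_POSITIVE_MIN:
        call = Call.WILDTYPE
    else:
        call = Call.INCONCLUSIVE
    return AssayCall(assay=counts.assay, call=call)


def combine_assays(call_228: AssayCall, call_250: AssayCall) -> TertpStatus:
    """Combine the two assay calls into one per-lesion status.

    Mutated if either assay is mutated; wildtype only if both are wildtype;
    inconclusive otherwise.  Order of arguments does not matter, but the two
    calls must come from different assays.
    """
    if call_228.assay is call_250.assay:
        raise ValueError(f"two calls supplied for the same assay {call_228.assay.value}")
    variants = frozenset(c.assay for c in (call_228, call_250) if c.call is Call.MUTATED)
    if variants:
        return TertpStatus(Call.MUTATED, variants)
    if call_228.call is Call.WILDTYPE and call_250.call is Call.WILDTYPE:
        return TertpStatus(Call.WILDTYPE)
    return TertpStatus(Call.INCONCLUSIVE)
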