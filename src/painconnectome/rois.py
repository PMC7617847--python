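"""Pain-connectome region definitions, connection indexing, and subnetworks.

The pain connectome is modelled as 12 bilateral regions of interest (ROIs)
consistently engaged in pain processing: thalamus, primary and secondary
somatosensory cortices (SI, SII), anterior and posterior insula (aI, pI),
anterior and mid-cingulate cortices (ACC, MCC), amygdala, basal ganglia
(BG), orbitofrontal cortex (OFC), and ventrolateral and dorsolateral
prefrontal cortices (vlPFC, dlPFC).

Connections are unordered pairs of ROI *types* (hemispheres are averaged
upstream), giving C(12, 2) = 66 connections.  The canonical connection
order is ``itertools.combinations`` over :data:`ROI_TYPES`, and a
connection id is the string ``"A-B"`` with A preceding B in that list.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

ROI_TYPES: tuple[str, ...] = (
    "thalamus",
    "SI",
    "SII",
    "aI",
    "pI",
    "ACC",
    "MCC",
    "amygdala",
    "BG",
    "OFC",
    "vlPFC",
    "dlPFC",
)

HEMISPHERES: tuple[str, str] = ("L", "R")

#: Column order of every time-series matrix: the 12 left-hemisphere ROIs in
#: :data:`ROI_TYPES` order, then the 12 right-hemisphere ROIs.
COLUMN_ORDER: tuple[str, ...] = tuple(
    f"{roi}_{hemi}" for hemi in HEMISPHERES for roi in ROI_TYPES
)


def connection_id(roi_a: str, roi_b: str) -> str:
    """Canonical id for the unordered pair (roi_a, roi_b).

    The two ROI types are sorted by their position in :data:`ROI_TYPES` and
    joined with ``-``, so ``connection_id("SI", "thalamus")`` and
    ``connection_id("thalamus", "SI")`` both return ``"thalamus-SI"``.
    """
    if roi_a == roi_b:
        raise ValueError(f"self-pair is not a connection: {roi_a!r}")
    for roi in (roi_a, roi_b):
        if roi not in ROI_TYPES:
            raise ValueError(f"unknown ROI type: {roi!r}")
    a, b = sorted((roi_a, roi_b), key=ROI_TYPES.index)
    return f"{a}-{b}"


@dataclass(frozen=True)
class ConnectionIndex:
    """Ordered list of the 66 unordered ROI-type pairs.

    Attributes
    ----------
    pairs
        Tuples ``(roi_a, roi_b)`` in canonical order.
    ids
        The matching ``"A-B"`` connection-id strings.
    """

    pairs: tuple[tuple[str, str], ...] = field(
        default=tuple(itertools.combinations(ROI_TYPES, 2))
    )

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair in connection index: {a}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate pair in connection index: {a}-{b}")
            seen.add(key)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(connection_id(a, b) for a, b in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def position(self, roi_a: str, roi_b: str) -> int:
        """Index of the unordered pair within the canonical order."""
        cid = connection_id(roi_a, roi_b)
        return self.ids.index(cid)


#: The default 66-connection index over the 12 pain-connectome ROI types.
CONNECTIONS = ConnectionIndex()


@dataclass(frozen=True)
class SubnetworkDefinition:
    """A named ROI set and its derived within-set connection list."""

    name: str
    roi_set: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.roi_set - set(ROI_TYPES)
        if unknown:
            raise ValueError(f"unknown ROI types in subnetwork: {sorted(unknown)}")

    @property
    def connections(self) -> tuple[str, ...]:
        """Connection ids of all unordered pairs within the ROI set."""
        members = [r for r in ROI_TYPES if r in self.roi_set]
        return tuple(
            connection_id(a, b) for a, b in itertools.combinations(members, 2)
        )


# The three functional subdivisions of the pain connectome. Regions may
# belong to several subnetworks (e.g. thalamus-BG sits in both sensory and
# affective), so connection families legitimately overlap.
SENSORY = SubnetworkDefinition("sensory", frozenset({"SI", "SII", "thalamus", "BG", "pI"}))
AFFECTIVE = SubnetworkDefinition(
    "affective", frozenset({"aI", "ACC", "thalamus", "amygdala", "BG"})
)
COGNITIVE = SubnetworkDefinition(
    "cognitive", frozenset({"dlPFC", "vlPFC", "OFC", "MCC", "BG", "aI"})
)

SUBNETWORKS: tuple[SubnetworkDefinition, ...] = (SENSORY, AFFECTIVE, COGNITIVE)
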