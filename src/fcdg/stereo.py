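"""Configuration keys and configurational-family grouping.

Each free stereo element (stereocenter or tracked diastereotopic group)
contributes one sign — the sign of its chiral volume in the canonical
atom-index ordering — to the configuration key, a string over {+, -}.  Keys
are internal labels, not CIP descriptors: the mapping to R/S nomenclature is
a separate reporting concern.  Classification is rotation/translation
invariant; under coordinate inversion all signs complement, and restoring the
fixed reference element's sign canonicalizes mirror images onto one key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import StructureRecord
from .energy import chiral_volume
from .moltop import StereoElement
from .moltop import free_elements as _free

__all__ = ["AmbiguousClassificationError", "ConfigurationFamily", "classify", "group"]

PLANARITY_TOL = 1e-6


class AmbiguousClassificationError(ValueError):
    def __init__(self, element: StereoElement, volume: float):
        self.element = element
        super().__init__(
            f"chiral volume of {element.label()} is {volume:.2e} Å^3 "
            f"(|V| <= {PLANARITY_TOL}); configuration is ambiguous"
        )


@dataclass
class ConfigurationFamily:
    key: str
    members: list[int] = field(default_factory=list)   # indices into the ensemble
    count: int = 0
    best_etotal: float = np.inf
    best_member: int = -1


def _sign(v: float, element: StereoElement) -> int:
    if abs(v) <= PLANARITY_TOL:
        raise AmbiguousClassificationError(element, v)
    return 1 if v > 0 else -1


def classify(coords: np.ndarray, elements: list[StereoElement]) -> str:
    """Configuration key of a structure: one {+,-} per free stereo element.

    If the fixed reference element comes out mirrored (negative volume), the
    whole key is complemented (inversion canonicalization), so enantiomeric
    coordinate sets map to the same key.
    """
    coords = np.asarray(coords, float)
    parity = 1
    fixed_refs = [e for e in elements if e.fixed and e.kind != "sp2-planar"]
    if fixed_refs:
        v, _ = chiral_volume(coords, fixed_refs[0])
        parity = _sign(v, fixed_refs[0])
    signs = []
    for e in _free(elements):
        v, _ = chiral_volume(coords, e)
        signs.append(_sign(v, e) * parity)
    return "".join("+" if s > 0 else "-" for s in signs)


def group(records: list[StructureRecord]) -> dict[str, ConfigurationFamily]:
    """Partition a classified ensemble into configurational families.

    Families are disjoint and exhaustive (counts sum to the ensemble size) and
    are returned ordered by their best (lowest) total pseudo-energy.
    """
    fams: dict[str, ConfigurationFamily] = {}
    for idx, rec in enumerate(records):
        if rec.configuration is None:
            raise ValueError(f"record {idx} is not classified")
        fam = fams.setdefault(rec.configuration, ConfigurationFamily(rec.configuration))
        fam.members.append(idx)
        fam.count += 1
        e = rec.energy.etotal
        if e < fam.best_etotal:
            fam.best_etotal = e
            fam.best_member = idx
    return dict(sorted(fams.items(), key=lambda kv: kv[1].best_etotal))
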