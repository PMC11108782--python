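"""Biomarker panel definitions.

A panel is the ordered set of candidate "events": CSF analytes that switch
from a normal to an abnormal regime at some point of disease progression.
Each biomarker carries a direction: whether raw abnormality manifests as a
decrease (the CSF Abeta42/40 ratio falls as amyloid plaques sequester
Abeta42) or an increase (phospho-occupancy ratios and tau fragments rise).
"""

from __future__ import annotations

from dataclasses import dataclass, field


DECREASE = "decrease"
INCREASE = "increase"


@dataclass(frozen=True)
class BiomarkerPanel:
    """Named biomarkers with their raw abnormality directions.

    Parameters
    ----------
    names
        Unique biomarker identifiers, also the column names expected in a
        cohort table.
    directions
        Mapping name -> "increase" or "decrease"; the sign applied when
        converting raw z-scores to the abnormality scale (higher = more
        abnormal).
    """

    names: tuple[str, ...]
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("biomarker names must be unique")
        for name in self.names:
            d = self.directions.get(name)
            if d not in (INCREASE, DECREASE):
                raise ValueError(
                    f"direction missing or invalid for biomarker {name!r}: {d!r}"
                )

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def sign(self, name: str) -> float:
        """+1 for increasing markers, -1 for decreasing ones."""
        return -1.0 if self.directions[name] == DECREASE else 1.0

    def subset(self, keep: list[str] | tuple[str, ...]) -> "BiomarkerPanel":
        """Panel restricted to ``keep``, preserving this panel's order."""
        missing = [n for n in keep if n not in self.names]
        if missing:
            raise KeyError(f"unknown biomarkers: {missing}")
        names = tuple(n for n in self.names if n in set(keep))
        return BiomarkerPanel(names, {n: self.directions[n] for n in names})

    def drop(self, remove: list[str] | tuple[str, ...]) -> "BiomarkerPanel":
        """Panel with ``remove`` taken out."""
        keep = [n for n in self.names if n not in set(remove)]
        return self.subset(keep)

    def to_dict(self) -> dict:
        return {"names": list(self.names), "directions": dict(self.directions)}

    @classmethod
    def from_dict(cls, d: dict) -> "BiomarkerPanel":
        return cls(tuple(d["names"]), dict(d["directions"]))


def default_panel() -> BiomarkerPanel:
    """The five-marker staging panel: Abeta42/40, pT217/T217, pT205/T205,
    MTBR-tau243 and non-phosphorylated mid-region tau."""
    names = ("Ab42_40", "pT217_T217", "pT205_T205", "MTBR_tau243", "np_tau")
    directions = {n: INCREASE for n in names}
    directions["Ab42_40"] = DECREASE
    return BiomarkerPanel(names, directions)


def full_panel() -> BiomarkerPanel:
    """Seven candidate markers: the staging five plus pT181/T181 and
    pT231/T231 (candidates for removal during model optimization)."""
    base = default_panel()
    names = base.names + ("pT181_T181", "pT231_T231")
    directions = dict(base.directions)
    directions["pT181_T181"] = INCREASE
    directions["pT231_T231"] = INCREASE
    return BiomarkerPanel(names, directions)
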