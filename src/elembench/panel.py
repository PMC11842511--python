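"""Element panel definition: which elements are measured and their LOQs.

The default panel is the 11-element trace/macro panel measured by ICP-MS in
muskox qiviut (undercoat hair): three macro elements (Na, Mg, Ca) and eight
trace elements (Cr, Mn, Fe, Co, Cu, Zn, Se, Mo), all in µg/g dry hair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

ELEMENTS: tuple[str, ...] = (
    "Na", "Mg", "Ca", "Cr", "Mn", "Fe", "Co", "Cu", "Zn", "Se", "Mo",
)

#: Default limits of quantitation (µg/g). Instrument LOQs are assay-specific
#: and must normally be supplied by the laboratory; these defaults are
#: plausible ICP-MS values for hair matrices, well below typical qiviut
#: concentrations for every element.
DEFAULT_LOQ: dict[str, float] = {
    "Na": 1.0,
    "Mg": 0.5,
    "Ca": 2.0,
    "Cr": 0.05,
    "Mn": 0.02,
    "Fe": 1.0,
    "Co": 0.005,
    "Cu": 0.05,
    "Zn": 0.5,
    "Se": 0.05,
    "Mo": 0.01,
}


class PanelConfigError(ValueError):
    """Raised when a panel or LOQ configuration is inconsistent."""


@dataclass(frozen=True)
class ElementPanel:
    """An ordered set of element names with optional per-element LOQs.

    Parameters
    ----------
    names:
        Ordered, unique element identifiers.
    loq:
        Map from element name to limit of quantitation (µg/g, >= 0). Keys
        must be a subset of ``names``; elements without an LOQ cannot carry
        below-LOQ flags through substitution.
    """

    names: tuple[str, ...] = ELEMENTS
    loq: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise PanelConfigError("panel element names must be unique")
        for el, q in dict(self.loq).items():
            if el not in names:
                raise PanelConfigError(f"LOQ given for unknown element {el!r}")
            if not (q >= 0):
                raise PanelConfigError(f"LOQ for {el!r} must be nonnegative, got {q}")

    def __contains__(self, el: str) -> bool:
        return el in self.names

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


def default_panel() -> ElementPanel:
    """The standard 11-element qiviut panel with default LOQs."""
    return ElementPanel(names=ELEMENTS, loq=dict(DEFAULT_LOQ))
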