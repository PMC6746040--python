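"""Panel definitions: channels, roles, spillover and transforms.

A *panel* is one fixed antibody/fluorochrome combination.  Four panel
fixtures mirror a routine acute-leukemia setup — two AML and two ALL
combinations of 10 fluorescence markers plus forward scatter, side
scatter and time.  Marker names are generic CD nomenclature; the
clustering space is the 10 fluorescences plus side scatter (11
dimensions), with forward scatter and time excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigurationError

ROLES = ("fluorescence", "side_scatter", "forward_scatter", "time")

#: Default arcsinh cofactors per role.  Side scatter spans a far larger
#: dynamic range than fluorescence, hence its larger cofactor.
DEFAULT_COFACTORS = {
    "fluorescence": 150.0,
    "side_scatter": 10_000.0,
}


@dataclass
class ChannelDef:
    name: str            # detector id ($PnN), e.g. "FL3"
    marker: str          # stain label ($PnS), e.g. "CD34"; "" for scatter/time
    role: str            # one of ROLES

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown channel role {self.role!r}")

    @property
    def display(self) -> str:
        return self.marker if self.marker else self.name


@dataclass
class PanelDefinition:
    """One antibody combination plus its processing parameters.

    ``spillover`` is a square matrix over the fluorescence channels (row =
    source stain, column = detector) used for compensation; ``None`` means
    the data are already compensated at acquisition.  ``cofactors`` maps a
    channel name to its arcsinh cofactor, defaulting per role.
    ``include_forward_scatter`` widens the clustering space beyond the
    default fluorescence + SSC set.
    """

    name: str
    channels: list[ChannelDef]
    spillover: np.ndarray | None = None
    cofactors: dict[str, float] = field(default_factory=dict)
    include_forward_scatter: bool = False

    def __post_init__(self) -> None:
        if self.spillover is not None:
            self.spillover = np.asarray(self.spillover, dtype=float)
            nf = len(self.fluorescence_channels())
            if self.spillover.shape != (nf, nf):
                raise ConfigurationError(
                    f"spillover shape {self.spillover.shape} does not match "
                    f"{nf} fluorescence channels"
                )
            if not np.allclose(np.diag(self.spillover), 1.0):
                raise ConfigurationError("spillover diagonal must be 1")
        for ch in self.channels:
            cf = self.cofactor(ch)
            if cf is not None and cf <= 0:
                raise ConfigurationError(f"non-positive cofactor for {ch.display}")

    # ------------------------------------------------------------------
    def fluorescence_channels(self) -> list[ChannelDef]:
        return [c for c in self.channels if c.role == "fluorescence"]

    def side_scatter_channel(self) -> ChannelDef | None:
        for c in self.channels:
            if c.role == "side_scatter":
                return c
        return None

    def clustering_channels(self) -> list[ChannelDef]:
        """Channels the SOM operates on: fluorescence + SSC (+FSC if opted in)."""
        keep = ["fluorescence", "side_scatter"]
        if self.include_forward_scatter:
            keep.append("forward_scatter")
        return [c for c in self.channels if c.role in keep]

    def cofactor(self, ch: ChannelDef) -> float | None:
        """arcsinh cofactor for a channel; None for identity (FSC/time)."""
        if ch.name in self.cofactors:
            return float(self.cofactors[ch.name])
        if ch.display in self.cofactors:
            return float(self.cofactors[ch.display])
        return DEFAULT_COFACTORS.get(ch.role)

    def marker_names(self) -> list[str]:
        return [c.display for c in self.clustering_channels()]

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "channels": [
                {"name": c.name, "marker": c.marker, "role": c.role}
                for c in self.channels
            ],
            "spillover": None if self.spillover is None else self.spillover.tolist(),
            "cofactors": dict(self.cofactors),
            "include_forward_scatter": self.include_forward_scatter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelDefinition":
        return cls(
            name=d["name"],
            channels=[ChannelDef(**c) for c in d["channels"]],
            spillover=None if d.get("spillover") is None else np.asarray(d["spillover"]),
            cofactors=dict(d.get("cofactors", {})),
            include_forward_scatter=bool(d.get("include_forward_scatter", False)),
        )

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "PanelDefinition":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ScalingStats:
    """Frozen per-channel location/spread used to standardize events.

    Computed once on the merged normal cohort and stored in the reference
    template, then applied verbatim to every patient sample so that node
    identity is comparable across samples.
    """

    channels: list[str]
    location: np.ndarray
    spread: np.ndarray
    spread_floor: float = 1e-6

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        if not (len(self.channels) == self.location.size == self.spread.size):
            raise ConfigurationError("scaling stats channel/location/spread mismatch")
        if np.any(self.spread < self.spread_floor):
            raise ConfigurationError("spread below floor; stats were not floored")

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "location": self.location.tolist(),
            "spread": self.spread.tolist(),
            "spread_floor": self.spread_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingStats":
        return cls(
            channels=list(d["channels"]),
            location=np.asarray(d["location"], dtype=float),
            spread=np.asarray(d["spread"], dtype=float),
            spread_floor=float(d.get("spread_floor", 1e-6)),
        )


# ----------------------------------------------------------------------
# Panel fixtures.  Marker lists are generic emulations of four 10-color
# acute-leukemia combinations; they are synthetic design choices, not
# reproductions of any published reagent table.

_PANEL_MARKERS = {
    "AML-A": ["CD45", "CD34", "CD38", "CD117", "CD13", "CD33",
              "HLA-DR", "CD14", "CD16", "CD64"],
    "AML-B": ["CD45", "CD34", "CD38", "CD117", "CD13", "CD33",
              "HLA-DR", "CD7", "CD56", "CD19"],
    "ALL-A": ["CD45", "CD34", "CD38", "CD19", "CD10", "CD20",
              "CD22", "CD58", "CD123", "CD81"],
    "ALL-B": ["CD45", "CD34", "CD38", "CD7", "CD5", "CD3",
              "CD2", "CD1a", "CD4", "CD8"],
}

PANEL_NAMES = tuple(_PANEL_MARKERS)


def _default_spillover(n: int, bleed: float = 0.06) -> np.ndarray:
    """Mild nearest-neighbor spillover between adjacent detectors."""
    s = np.eye(n)
    for i in range(n - 1):
        s[i, i + 1] = bleed
        s[i + 1, i] = bleed / 2
    return s


def default_panel(name: str = "AML-B") -> PanelDefinition:
    """Return one of the four bundled panel fixtures."""
    if name not in _PANEL_MARKERS:
        raise ConfigurationError(
            f"unknown panel {name!r}; available: {sorted(_PANEL_MARKERS)}"
        )
    markers = _PANEL_MARKERS[name]
    channels = [ChannelDef("FSC", "", "forward_scatter"),
                ChannelDef("SSC", "", "side_scatter")]
    channels += [
        ChannelDef(f"FL{i + 1}", m, "fluorescence") for i, m in enumerate(markers)
    ]
    channels.append(ChannelDef("TIME", "", "time"))
    return PanelDefinition(
        name=name,
        channels=channels,
        spillover=_default_spillover(len(markers)),
    )
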