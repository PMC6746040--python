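"""Event-level cytometry data container.

An :class:`EventMatrix` is the in-memory list-mode table: one row per
measured cell ("event"), one column per detector channel, plus per-event
sample-of-origin labels and a processing-state flag that the pipeline
advances (``raw -> compensated -> transformed -> scaled``).  Synthetic data
additionally carry a hidden population-of-origin truth array used only by
tests and purity diagnostics, never by the analysis itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Allowed processing states, in pipeline order.
STATES = ("raw", "compensated", "transformed", "scaled")

#: Column name used for the hidden truth labels in CSV round-trips.
TRUTH_COLUMN = "__population"


@dataclass
class EventMatrix:
    """Events x channels measurement table.

    Parameters
    ----------
    values
        Float matrix of shape ``(n_events, n_channels)``; arbitrary
        fluorescence/scatter units depending on ``state``.
    channel_names
        Short detector identifiers (``$PnN``), one per column.
    marker_names
        Stain/marker labels (``$PnS``); may be ``""`` for unstained
        channels such as scatter or time.
    sample_ids
        Per-event sample-of-origin label.
    state
        One of ``raw``, ``compensated``, ``transformed``, ``scaled``.
    truth
        Optional per-event population-of-origin labels (synthetic data only).
    """

    values: np.ndarray
    channel_names: list[str]
    marker_names: list[str] = field(default_factory=list)
    sample_ids: np.ndarray | None = None
    state: str = "raw"
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {self.values.shape}")
        n, c = self.values.shape
        self.channel_names = [str(x) for x in self.channel_names]
        if len(self.channel_names) != c:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {c} columns"
            )
        if not self.marker_names:
            self.marker_names = [""] * c
        self.marker_names = [str(x) for x in self.marker_names]
        if len(self.marker_names) != c:
            raise ValidationError(
                f"{len(self.marker_names)} marker names for {c} columns"
            )
        if self.sample_ids is None:
            self.sample_ids = np.array(["sample0"] * n, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.sample_ids.shape != (n,):
            raise ValidationError(
                f"sample_ids length {self.sample_ids.shape} does not match {n} events"
            )
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValidationError("values contain non-finite entries")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=object)
            if self.truth.shape != (n,):
                raise ValidationError("truth length does not match event count")

    # ------------------------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "EventMatrix":
        return replace(
            self,
            values=self.values.copy(),
            channel_names=list(self.channel_names),
            marker_names=list(self.marker_names),
            sample_ids=self.sample_ids.copy(),
            truth=None if self.truth is None else self.truth.copy(),
        )

    def with_values(self, values: np.ndarray, state: str | None = None) -> "EventMatrix":
        """Return a copy with new values (and optionally a new state)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            state=self.state if state is None else state,
            channel_names=list(self.channel_names),
            marker_names=list(self.marker_names),
            sample_ids=self.sample_ids.copy(),
            truth=None if self.truth is None else self.truth.copy(),
        )

    def column_index(self, name: str) -> int:
        """Locate a column by marker name, falling back to channel name.

        Matching is case-insensitive; marker labels take precedence because
        the same stain may sit on different detectors across instruments.
        """
        key = name.strip().lower()
        for i, m in enumerate(self.marker_names):
            if m.strip().lower() == key and key:
                return i
        for i, cnm in enumerate(self.channel_names):
            if cnm.strip().lower() == key:
                return i
        raise ChannelLookupError(name)

    def display_names(self) -> list[str]:
        """Marker name where present, else channel name — for reports."""
        return [
            m if m.strip() else c
            for m, c in zip(self.marker_names, self.channel_names)
        ]

    # ------------------------------------------------------------------
    def to_dataframe(self, include_truth: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channel_names)
        df["__sample"] = self.sample_ids
        if include_truth and self.truth is not None:
            df[TRUTH_COLUMN] = self.truth
        return df


class ChannelLookupError(ValidationError, KeyError):
    """Raised when a requested channel/marker is absent from an EventMatrix."""

    def __init__(self, name: str):
        super().__init__(f"channel or marker {name!r} not found")
        self.channel = name


# ----------------------------------------------------------------------
# CSV dialect: first header row = channel names, optional second header
# row = marker names (prefixed '#markers:'), then one row per event.
# Sample ids and truth labels ride along as reserved columns.

def write_csv(events: EventMatrix, path) -> None:
    """Write an EventMatrix to the package's CSV event-table dialect."""
    with open(path, "w") as fh:
        cols = list(events.channel_names) + ["__sample"]
        if events.truth is not None:
            cols.append(TRUTH_COLUMN)
        fh.write(",".join(cols) + "\n")
        fh.write("#markers:" + ",".join(events.marker_names) + "\n")
        df = events.to_dataframe()
        df.to_csv(fh, header=False, index=False)


def read_csv(path, state: str = "raw") -> EventMatrix:
    """Read the CSV event-table dialect written by :func:`write_csv`.

    Plain CSVs without the marker row are accepted (markers default to
    empty); this is a fixture convenience, not an interchange format.
    """
    with open(path) as fh:
        header = fh.readline().strip()
        pos = fh.tell()
        second = fh.readline()
        markers = None
        if second.startswith("#markers:"):
            markers = second[len("#markers:"):].rstrip("\n").split(",")
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, header=None, names=header.split(","))
    channel_cols = [c for c in df.columns if c not in ("__sample", TRUTH_COLUMN)]
    values = df[channel_cols].to_numpy(dtype=float)
    sample_ids = (
        df["__sample"].to_numpy(dtype=object)
        if "__sample" in df.columns
        else None
    )
    truth = df[TRUTH_COLUMN].to_numpy(dtype=object) if TRUTH_COLUMN in df.columns else None
    if markers is not None:
        markers = markers[: len(channel_cols)]
    return EventMatrix(
        values=values,
        channel_names=channel_cols,
        marker_names=markers or [],
        sample_ids=sample_ids,
        state=state,
        truth=truth,
    )
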