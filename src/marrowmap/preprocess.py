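"""Compensation, arcsinh transformation and channel selection/scaling.

The pipeline advances an :class:`~marrowmap.events.EventMatrix` through
``raw -> compensated -> transformed -> scaled``:

1. **compensate** — remove fluorescence spillover between detectors by
   right-multiplying with the inverse spillover matrix.
2. **transform** — arcsinh with a per-channel cofactor, the standard
   variance-stabilizing transform for cytometry; side scatter gets its
   own (much larger) cofactor so its dynamic range matches fluorescence.
3. **select_and_scale** — keep the clustering channels (all fluorescences
   plus side scatter; 11 dimensions on a 10-color panel), and standardize
   each with a robust location (median) and spread (SD, floored).  In
   mapping mode the frozen statistics of a reference template are applied
   unchanged so patient samples land in the reference coordinate system.
"""

from __future__ import annotations

import logging

import numpy as np

from .events import EventMatrix
from .exceptions import ChannelMismatchError, ConfigurationError, NumericalError
from .panel import ChannelDef, PanelDefinition, ScalingStats

logger = logging.getLogger(__name__)

#: Condition number above which a spillover matrix is treated as singular.
_MAX_SPILLOVER_COND = 1e12


def _panel_column(events: EventMatrix, ch: ChannelDef) -> int:
    """Column index of a panel channel, matching marker then channel name."""
    for key in (ch.marker, ch.name):
        if not key:
            continue
        try:
            return events.column_index(key)
        except KeyError:
            continue
    sample = events.sample_ids[0] if events.n_events else "<empty>"
    raise ChannelMismatchError(
        f"sample {sample!r} is missing panel channel {ch.display!r}"
    )


def compensate(events: EventMatrix, panel: PanelDefinition) -> EventMatrix:
    """Apply spillover compensation to the fluorescence channels.

    With observed = true @ S (S rows = source stain, columns = detector),
    the compensated values are observed @ S^-1.  Scatter and time columns
    are untouched.  Panels without a spillover matrix pass through with
    only the state advanced.
    """
    if events.state != "raw":
        raise ConfigurationError(f"compensate expects raw events, got {events.state}")
    out = events.values.copy()
    if panel.spillover is not None:
        s = panel.spillover
        if np.linalg.cond(s) > _MAX_SPILLOVER_COND:
            raise NumericalError(
                f"spillover matrix of panel {panel.name!r} is singular or "
                f"near-singular (cond={np.linalg.cond(s):.3g})"
            )
        cols = [_panel_column(events, ch) for ch in panel.fluorescence_channels()]
        observed = out[:, cols]
        # observed @ inv(S) via a linear solve for accuracy
        out[:, cols] = np.linalg.solve(s.T, observed.T).T
    return events.with_values(out, state="compensated")


def transform(events: EventMatrix, panel: PanelDefinition) -> EventMatrix:
    """arcsinh-transform fluorescence and side scatter channels in place.

    ``x -> arcsinh(x / cofactor)``; monotone, linear near zero and
    logarithmic for large x.  Channels whose role carries no cofactor
    (forward scatter, time) are left on their original scale.
    """
    if events.state not in ("compensated", "raw"):
        raise ConfigurationError(
            f"transform expects raw or compensated events, got {events.state}"
        )
    if events.state == "raw" and panel.spillover is not None:
        raise ConfigurationError(
            "panel declares a spillover matrix; compensate before transforming"
        )
    out = events.values.copy()
    for ch in panel.channels:
        cf = panel.cofactor(ch)
        if cf is None:
            continue
        if cf <= 0:
            raise ConfigurationError(f"non-positive cofactor for {ch.display}")
        j = _panel_column(events, ch)
        out[:, j] = np.arcsinh(out[:, j] / cf)
    return events.with_values(out, state="transformed")


def inverse_transform(events: EventMatrix, panel: PanelDefinition) -> EventMatrix:
    """Invert :func:`transform` (sinh), returning compensated-scale values."""
    if events.state != "transformed":
        raise ConfigurationError(
            f"inverse_transform expects transformed events, got {events.state}"
        )
    out = events.values.copy()
    for ch in panel.channels:
        cf = panel.cofactor(ch)
        if cf is None:
            continue
        j = _panel_column(events, ch)
        out[:, j] = np.sinh(out[:, j]) * cf
    return events.with_values(out, state="compensated")


def select_and_scale(
    events: EventMatrix,
    panel: PanelDefinition,
    stats: ScalingStats | None = None,
    spread_floor: float = 1e-6,
) -> tuple[EventMatrix, ScalingStats]:
    """Select the clustering channels and standardize them.

    Retains all fluorescence channels plus side scatter, in panel order
    (forward scatter and time are dropped unless the panel opts FSC in).
    When ``stats`` is ``None``, per-channel median and standard deviation
    (floored at ``spread_floor``) are computed from the data; otherwise
    the supplied statistics are applied verbatim — the mapping mode used
    for patient samples against a frozen reference.
    """
    if events.state != "transformed":
        raise ConfigurationError(
            f"select_and_scale expects transformed events, got {events.state}"
        )
    chans = panel.clustering_channels()
    names = [c.display for c in chans]
    cols = [_panel_column(events, c) for c in chans]
    sub = events.values[:, cols]

    if stats is None:
        location = np.median(sub, axis=0) if len(sub) else np.zeros(len(cols))
        spread = sub.std(axis=0, ddof=0) if len(sub) else np.ones(len(cols))
        degenerate = spread < spread_floor
        if degenerate.any():
            logger.warning(
                "constant channel(s) %s: spread floored at %g",
                [names[i] for i in np.flatnonzero(degenerate)],
                spread_floor,
            )
        spread = np.maximum(spread, spread_floor)
        stats = ScalingStats(
            channels=names, location=location, spread=spread, spread_floor=spread_floor
        )
    else:
        if list(stats.channels) != names:
            raise ConfigurationError(
                f"scaling stats channels {stats.channels} do not match panel "
                f"clustering channels {names}"
            )
    scaled = (sub - stats.location) / stats.spread
    out = EventMatrix(
        values=scaled,
        channel_names=[chans[i].name for i in range(len(chans))],
        marker_names=[chans[i].marker for i in range(len(chans))],
        sample_ids=events.sample_ids.copy(),
        state="scaled",
        truth=None if events.truth is None else events.truth.copy(),
    )
    return out, stats
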