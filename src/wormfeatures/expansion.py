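"""Expansion of core features into the full phenotypic fingerprint.

Each core feature channel (a base feature, optionally localized to a body
segment and optionally length-normalized) is expanded by taking the time
derivative, subdividing by motion state (forward / backward / paused),
optionally taking the absolute value of signed series, and summarizing each
resulting series by its 10th, 50th and 90th percentiles.  Motion mode is
summarized instead by event statistics (fraction of time, entry frequency).

Feature names follow a fixed grammar, e.g. ``d_curvature_hips_w_forward_abs_90th``
is the 90th percentile of the absolute rate of change of hip curvature while
moving forward.  The default inventory enumerates 4083 names from 16 base
features; the reduced presets (tierpsy_8, tierpsy_16, tierpsy_2k) are
restrictions of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from . import core
from .core import (
    DEFAULT_PARAMS,
    BodySegmentMap,
    CoreSeries,
    MotionStateSeries,
    SEGMENT_NAMES,
    RELATIVE_VELOCITY_PAIRS,
)
from .io import ValidationError, WormTrajectory

PERCENTILES = ("10th", "50th", "90th")
EVENT_STATS = ("fraction", "frequency")
MOTION_STATES = ("forward", "backward", "paused")

_SEGMENT_TOKENS = (
    "head_base",
    "tail_base",
    "head_tip",
    "tail_tip",
    "midbody",
    "head",
    "neck",
    "hips",
    "tail",
    "body",
)


@dataclass(frozen=True)
class FeatureName:
    """Structured feature name, round-trippable to and from its string form."""

    base: str
    segment: str | None = None
    derivative: bool = False
    motion_state: str | None = None
    sign: str = "signed"  # "signed" (as computed) or "abs"
    normalized: bool = False
    summary: str = "50th"

    def __post_init__(self) -> None:
        if self.summary not in PERCENTILES + EVENT_STATS:
            raise ValidationError(f"unknown summary {self.summary!r}")
        if self.sign not in ("signed", "abs"):
            raise ValidationError(f"unknown sign {self.sign!r}")
        if self.summary in EVENT_STATS:
            if self.motion_state is None:
                raise ValidationError("event statistics require a motion state")
            if self.derivative or self.normalized or self.sign == "abs":
                raise ValidationError(
                    "event statistics do not combine with derivative/norm/abs"
                )
        if self.motion_state is not None and self.motion_state not in MOTION_STATES:
            raise ValidationError(f"unknown motion state {self.motion_state!r}")

    def render(self) -> str:
        if self.summary in EVENT_STATS:
            return f"{self.base}_{self.motion_state}_{self.summary}"
        parts = []
        if self.derivative:
            parts.append("d")
        parts.append(self.base)
        if self.segment is not None:
            parts.append(self.segment)
        if self.normalized:
            parts.append("norm")
        if self.motion_state is not None:
            parts.append(f"w_{self.motion_state}")
        if self.sign == "abs":
            parts.append("abs")
        parts.append(self.summary)
        return "_".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        original = name
        for stat in EVENT_STATS:
            if name.endswith("_" + stat):
                rest = name[: -len(stat) - 1]
                for state in MOTION_STATES:
                    if rest.endswith("_" + state):
                        return cls(
                            base=rest[: -len(state) - 1],
                            motion_state=state,
                            summary=stat,
                        )
                raise ValidationError(f"cannot parse event feature {original!r}")
        derivative = name.startswith("d_")
        if derivative:
            name = name[2:]
        summary = None
        for pct in PERCENTILES:
            if name.endswith("_" + pct):
                summary = pct
                name = name[: -len(pct) - 1]
                break
        if summary is None:
            raise ValidationError(f"{original!r} has no percentile or event summary")
        sign = "signed"
        if name.endswith("_abs"):
            sign = "abs"
            name = name[:-4]
        motion_state = None
        for state in MOTION_STATES:
            tok = f"_w_{state}"
            if name.endswith(tok):
                motion_state = state
                name = name[: -len(tok)]
                break
        normalized = False
        if name.endswith("_norm"):
            normalized = True
            name = name[:-5]
        segment = None
        for tok in _SEGMENT_TOKENS:
            if name.endswith("_" + tok):
                segment = tok
                name = name[: -len(tok) - 1]
                break
        else:
            head, _, tail = name.rpartition("_")
            if head and tail.isdigit():
                segment, name = tail, head
        if not name:
            raise ValidationError(f"{original!r} has no base feature")
        return cls(
            base=name,
            segment=segment,
            derivative=derivative,
            motion_state=motion_state,
            sign=sign,
            normalized=normalized,
            summary=summary,
        )


@dataclass
class Fingerprint:
    """One worm's mapping of feature-name string to summary value."""

    worm_id: str
    values: dict[str, float] = field(default_factory=dict)

    def as_array(self, names: list[str]) -> np.ndarray:
        return np.array([self.values.get(n, np.nan) for n in names])


# ---------------------------------------------------------------------------
# inventory configuration


def _channel(
    base: str,
    segment: str | None = None,
    *,
    norm: bool = False,
    signed: bool = False,
    dorsoventral: bool = False,
    derivative: bool = True,
    state_split: bool = True,
    abs_only: bool = False,
) -> dict:
    return {
        "base": base,
        "segment": segment,
        "norm": norm,
        "signed": signed,
        "dorsoventral": dorsoventral,
        "derivative": derivative,
        "state_split": state_split,
        "abs_only": abs_only,
    }


def build_default_inventory() -> dict:
    """The shipped full inventory: 16 base features expanding to 4083 names."""
    channels: list[dict] = []
    # morphology (unsigned)
    channels.append(_channel("length"))
    for norm in (False, True):
        channels.append(_channel("area", norm=norm))
    for seg in SEGMENT_NAMES + ("head_base",):
        for norm in (False, True):
            channels.append(_channel("width", seg, norm=norm))
    for base in ("major_axis", "minor_axis"):
        for norm in (False, True):
            channels.append(_channel(base, norm=norm))
    channels.append(_channel("quirkiness"))
    # posture
    for seg in SEGMENT_NAMES:
        for norm in (False, True):
            channels.append(_channel("curvature", seg, norm=norm, signed=True, dorsoventral=True))
    for k in range(1, 8):
        channels.append(_channel("eigen_projection", str(k), signed=True, dorsoventral=True))
    # velocities
    anchors = SEGMENT_NAMES + ("head_tip", "tail_tip")
    for seg in anchors:
        for norm in (False, True):
            channels.append(_channel("speed", seg, norm=norm, signed=True))
    for seg in anchors:
        channels.append(_channel("angular_velocity", seg, signed=True, dorsoventral=True))
    for ref, mov in RELATIVE_VELOCITY_PAIRS:
        for norm in (False, True):
            channels.append(
                _channel(f"relative_to_{ref}_radial_velocity", mov, norm=norm, signed=True)
            )
    for ref, mov in RELATIVE_VELOCITY_PAIRS:
        channels.append(
            _channel(
                f"relative_to_{ref}_angular_velocity", mov, signed=True, dorsoventral=True
            )
        )
    # path: curvature keeps its derivative but, being a property of the track
    # rather than the body, is not subdivided by motion state; coverage and
    # dispersion are slow windowed quantities summarized by percentiles only
    for norm in (False, True):
        channels.append(
            _channel(
                "path_curvature",
                norm=norm,
                signed=True,
                dorsoventral=True,
                state_split=False,
            )
        )
    for seg in SEGMENT_NAMES + ("body",):
        channels.append(
            _channel("path_coverage", seg, derivative=False, state_split=False)
        )
    channels.append(_channel("dispersion", derivative=False, state_split=False))
    events = [
        {"base": "motion_mode", "state": state, "stats": list(EVENT_STATS)}
        for state in MOTION_STATES
    ]
    return {"channels": channels, "events": events}


def build_tierpsy2k_inventory() -> dict:
    """The symmetrized reduced inventory: no eigenworm amplitudes, no
    length-normalized duplicates beyond the widths, and only absolute values
    of dorsoventrally signed features."""
    full = build_default_inventory()
    channels = []
    for ch in full["channels"]:
        if ch["base"] == "eigen_projection":
            continue
        if ch["norm"] and ch["base"] != "width":
            continue
        ch = dict(ch)
        if ch["dorsoventral"]:
            ch["abs_only"] = True
        channels.append(ch)
    return {"channels": channels, "events": full["events"]}


def feature_inventory(preset: str = "full") -> dict:
    """Named inventory configurations.

    ``full`` and ``tierpsy_2k`` are generated; ``tierpsy_8`` and
    ``tierpsy_16`` are the published hand-picked lists; ``tierpsy_256``
    must be supplied by the user (its membership is not in the main text).
    """
    if preset == "full":
        with resources.files("wormfeatures.data").joinpath(
            "feature_inventory.json"
        ).open() as fh:
            return json.load(fh)
    if preset == "tierpsy_2k":
        return build_tierpsy2k_inventory()
    if preset in ("tierpsy_8", "tierpsy_16"):
        return {"names": load_feature_set(preset)}
    if preset == "tierpsy_256":
        raise FileNotFoundError(
            "the tierpsy_256 membership is published as supplementary data; "
            "supply it as a config of the form {'names': [...]}"
        )
    raise ValueError(f"unknown inventory preset {preset!r}")


def load_feature_set(name: str) -> list[str]:
    """Load a shipped reduced feature-name list (tierpsy_8 / tierpsy_16)."""
    path = resources.files("wormfeatures.data").joinpath(f"{name}.txt")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def generate_feature_names(config: dict) -> list[FeatureName]:
    """Deterministically enumerate the feature names of an inventory config."""
    if "names" in config:
        names = [FeatureName.parse(n) for n in config["names"]]
    else:
        names = []
        for ch in config["channels"]:
            derivs = (False, True) if ch.get("derivative", True) else (False,)
            states = (None,) + (MOTION_STATES if ch.get("state_split", True) else ())
            if ch.get("signed", False):
                signs = ("abs",) if ch.get("abs_only", False) else ("signed", "abs")
            else:
                signs = ("signed",)
            for deriv in derivs:
                for state in states:
                    for sign in signs:
                        for pct in PERCENTILES:
                            names.append(
                                FeatureName(
                                    base=ch["base"],
                                    segment=ch.get("segment"),
                                    derivative=deriv,
                                    motion_state=state,
                                    sign=sign,
                                    normalized=ch.get("norm", False),
                                    summary=pct,
                                )
                            )
        for ev in config.get("events", []):
            for stat in ev["stats"]:
                if stat not in EVENT_STATS:
                    raise ValidationError(
                        f"event base {ev['base']!r} cannot take summary {stat!r}"
                    )
                names.append(
                    FeatureName(base=ev["base"], motion_state=ev["state"], summary=stat)
                )
    rendered = [n.render() for n in names]
    if len(set(rendered)) != len(rendered):
        dupes = sorted({r for r in rendered if rendered.count(r) > 1})
        raise ValidationError(f"inventory produces duplicate names: {dupes[:5]}")
    return names


# ---------------------------------------------------------------------------
# series operations


def time_derivative(values: np.ndarray, timestamps: np.ndarray) -> np.ndarray:
    """Central-difference time derivative; NaN at the edges and next to
    invalid frames."""
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    if values.size >= 3:
        out[1:-1] = (values[2:] - values[:-2]) / (timestamps[2:] - timestamps[:-2])
    return out


def subdivide_by_state(
    values: np.ndarray, states: MotionStateSeries, state: str
) -> np.ndarray:
    """Copy of the series with NaN wherever the motion state differs."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != states.states.shape[0]:
        raise ValidationError("series and motion states differ in length")
    out = values.copy()
    out[states.states != state] = np.nan
    return out


def summarize(values: np.ndarray) -> dict[str, float]:
    """10th/50th/90th percentiles over the finite values (NaN if none)."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return {p: np.nan for p in PERCENTILES}
    q = np.percentile(finite, [10, 50, 90])
    return dict(zip(PERCENTILES, (float(v) for v in q)))


def event_statistics(
    states: MotionStateSeries, state: str, total_time: float
) -> dict[str, float]:
    """Fraction of defined time spent in a state and entries per second."""
    if not total_time > 0:
        raise ValidationError("total_time must be positive")
    labels = states.states
    defined = labels != "undefined"
    if not defined.any():
        return {"fraction": np.nan, "frequency": np.nan}
    in_state = labels == state
    fraction = float(in_state[defined].mean())
    entries = 0
    prev = False
    for flag in in_state:
        if flag and not prev:
            entries += 1
        prev = flag
    return {"fraction": fraction, "frequency": entries / total_time}


# ---------------------------------------------------------------------------
# fingerprint computation


class _CoreRegistry:
    """Lazily computes and caches the raw core series of one trajectory."""

    def __init__(
        self,
        traj: WormTrajectory,
        params: dict,
        basis: np.ndarray | None = None,
    ) -> None:
        self.traj = traj
        self.params = params
        self.basis = basis
        self.segmap = BodySegmentMap(traj.n_points)
        self._cache: dict[str, CoreSeries] = {}
        self._groups_done: set[str] = set()

    def _store(self, series) -> None:
        if isinstance(series, dict):
            series = series.values()
        elif isinstance(series, CoreSeries):
            series = [series]
        for s in series:
            self._cache[s.name] = s

    def get(self, name: str) -> CoreSeries:
        if name in self._cache:
            return self._cache[name]
        group = self._group_of(name)
        self._compute_group(group)
        if name not in self._cache:
            raise KeyError(f"unknown core series {name!r}")
        return self._cache[name]

    @staticmethod
    def _group_of(name: str) -> str:
        if name in ("length", "area"):
            return name
        for prefix in (
            "width",
            "curvature",
            "speed",
            "angular_velocity",
            "eigen_projection",
        ):
            if name.startswith(prefix):
                return prefix
        if name.startswith("relative_to_"):
            return "relative"
        if name.startswith(("path_", "dispersion")):
            return "path"
        if name in ("major_axis", "minor_axis", "quirkiness"):
            return "axes"
        return name

    def _compute_group(self, group: str) -> None:
        if group in self._groups_done:
            return
        traj, segmap, p = self.traj, self.segmap, self.params
        if group == "length":
            self._store(core.compute_length(traj))
        elif group == "area":
            self._store(core.compute_area(traj))
        elif group == "width":
            self._store(core.compute_widths(traj, segmap))
        elif group == "axes":
            self._store(core.compute_axes_and_quirkiness(traj))
        elif group == "curvature":
            self._store(core.compute_curvature(traj, segmap))
        elif group in ("speed", "angular_velocity"):
            self._store(core.compute_velocity(traj, segmap, p["velocity_window"]))
            self._groups_done.add("speed")
            self._groups_done.add("angular_velocity")
        elif group == "relative":
            for ref, mov in RELATIVE_VELOCITY_PAIRS:
                self._store(
                    core.compute_relative_velocity(
                        traj, segmap, mov, ref, p["velocity_window"]
                    )
                )
        elif group == "eigen_projection":
            basis = self.basis
            if basis is None:
                basis = core.default_eigenworm_basis(
                    traj.n_points - 1, p["n_eigenworms"]
                )
            self._store(core.compute_eigen_projections(traj, basis))
        elif group == "path":
            self._store(
                core.compute_path_features(
                    traj,
                    segmap,
                    window=p["path_window"],
                    coverage_window=p["coverage_window"],
                    cell_size=p["coverage_cell_um"],
                )
            )
        self._groups_done.add(group)

    def motion_states(self) -> MotionStateSeries:
        if not hasattr(self, "_states"):
            body_length = float(np.nanmedian(self.get("length").values))
            if not np.isfinite(body_length) or body_length <= 0:
                self._states = MotionStateSeries(
                    np.full(self.traj.n_frames, "undefined")
                )
            else:
                self._states = core.classify_motion_state(
                    self.get("speed_midbody"),
                    fps=self.traj.fps,
                    fwd_threshold=self.params["fwd_threshold_bl"] * body_length,
                    pause_threshold=self.params["pause_threshold_bl"] * body_length,
                    min_duration=self.params["min_bout_duration"],
                )
        return self._states


def _channel_series_name(ch: dict) -> str:
    if ch["segment"] is not None:
        return f"{ch['base']}_{ch['segment']}"
    return ch["base"]


def compute_fingerprint(
    traj: WormTrajectory,
    config: dict | None = None,
    params: dict | None = None,
    basis: np.ndarray | None = None,
) -> Fingerprint:
    """Expand and summarize a trajectory into its phenotypic fingerprint.

    Undefined quantities (missing widths, motion states that never occur,
    dorsoventrally signed values when the ventral side is unknown) yield NaN
    rather than raising.
    """
    if config is None:
        config = feature_inventory("full")
    merged = dict(DEFAULT_PARAMS)
    if params:
        merged.update(params)
    params = merged
    requested: list[str] | None = config.get("names")
    if requested is not None:
        config = _config_from_names(requested)
    registry = _CoreRegistry(traj, params, basis)
    states = registry.motion_states()
    length = registry.get("length").values
    dv_known = traj.ventral_side != "unknown"
    fp = Fingerprint(worm_id=traj.worm_id)
    for ch in config["channels"]:
        series = registry.get(_channel_series_name(ch))
        raw = series.values
        if ch.get("norm", False):
            with np.errstate(invalid="ignore", divide="ignore"):
                if "1/um" in series.units:
                    raw = raw * length
                else:
                    raw = raw / length
        derivs = (False, True) if ch.get("derivative", True) else (False,)
        state_opts = (None,) + (
            MOTION_STATES if ch.get("state_split", True) else ()
        )
        if ch.get("signed", False):
            signs = ("abs",) if ch.get("abs_only", False) else ("signed", "abs")
        else:
            signs = ("signed",)
        dv_masked = ch.get("dorsoventral", False) and not dv_known
        for deriv in derivs:
            base_series = (
                time_derivative(raw, traj.timestamps) if deriv else raw
            )
            for state in state_opts:
                sub = (
                    subdivide_by_state(base_series, states, state)
                    if state is not None
                    else base_series
                )
                for sign in signs:
                    if sign == "abs":
                        values = np.abs(sub)
                        stats = summarize(values)
                    elif dv_masked and ch.get("signed", False):
                        stats = {p: np.nan for p in PERCENTILES}
                    else:
                        stats = summarize(sub)
                    for pct, val in stats.items():
                        name = FeatureName(
                            base=ch["base"],
                            segment=ch.get("segment"),
                            derivative=deriv,
                            motion_state=state,
                            sign=sign,
                            normalized=ch.get("norm", False),
                            summary=pct,
                        )
                        fp.values[name.render()] = val
    defined = states.states != "undefined"
    total_time = defined.sum() / traj.fps
    for ev in config.get("events", []):
        if total_time > 0:
            stats = event_statistics(states, ev["state"], total_time)
        else:
            stats = {s: np.nan for s in ev["stats"]}
        for stat in ev["stats"]:
            name = FeatureName(base=ev["base"], motion_state=ev["state"], summary=stat)
            fp.values[name.render()] = stats[stat]
    if requested is not None:
        fp.values = {n: fp.values.get(n, np.nan) for n in requested}
    return fp


def _config_from_names(names: list[str]) -> dict:
    """Minimal channel config covering an explicit feature-name list."""
    parsed = [FeatureName.parse(n) for n in names]
    channels: dict[tuple, dict] = {}
    events: dict[str, dict] = {}
    full = {
        ( _channel_series_name(ch), ch["norm"]): ch
        for ch in build_default_inventory()["channels"]
    }
    for fn in parsed:
        if fn.summary in EVENT_STATS:
            ev = events.setdefault(
                fn.motion_state, {"base": fn.base, "state": fn.motion_state, "stats": []}
            )
            if fn.summary not in ev["stats"]:
                ev["stats"].append(fn.summary)
            continue
        series = fn.base if fn.segment is None else f"{fn.base}_{fn.segment}"
        key = (series, fn.normalized)
        if key not in channels:
            template = full.get(key)
            channels[key] = dict(template) if template else _channel(
                fn.base, fn.segment, norm=fn.normalized, signed=fn.sign == "abs"
            )
    config = {"channels": list(channels.values()), "events": list(events.values())}
    config["_names"] = [fn.render() for fn in parsed]
    return config


def fingerprint_names(config: dict) -> list[str]:
    """Rendered name list for a config (explicit lists keep their order)."""
    if "names" in config:
        return list(config["names"])
    return [n.render() for n in generate_feature_names(config)]
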