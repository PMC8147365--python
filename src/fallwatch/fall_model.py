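"""The 2D probabilistic map of human falling and its alarm logic.

Training data are fused (x, y, z, speed) trajectory points; the map
lives on a 2D projection of them (by default longitudinal position z and
overall speed, the two axes that separate staggering and falling from
walking).  The projected pair is decorrelated and whitened in the map
plane — projection happens before decorrelation, because whitening the
full feature space first would rotate the shared fall signal (image
centroid dropping while the range shifts) partly out of any axis-aligned
pair and collapse the cluster separation.  DDFT selects the cluster
number — two, normal motion and falling — and a two-component Gaussian
mixture then defines the state regions: within 1.5 Mahalanobis standard
deviations of the normal component is normal, within 1.5 of the fall
component is falling, and everything beyond both ellipses is the
transition region.  Entering the transition region raises the alarm; a
detected fall latches it and the tracker shuts off five seconds later.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import ddft
from .errors import ConfigurationError, ParameterError
from .fusion import FEATURE_NAMES, NormalizationModel, fit_normalization

log = logging.getLogger(__name__)

#: default 2D projection of the 4D normalized feature space
DEFAULT_PROJECTION = ("z", "speed")

SD_MULTIPLIER = 1.5
SHUTOFF_DELAY_S = 5.0

STATE_NORMAL = "normal"
STATE_TRANSITION = "transition"
STATE_FALL = "fall"


def projection_indices(projection: tuple[str, str],
                       feature_names=FEATURE_NAMES) -> tuple[int, int]:
    try:
        return tuple(feature_names.index(p) for p in projection)
    except ValueError as e:
        raise ConfigurationError(f"unknown projection feature: {e}") from e


@dataclass
class FallMap:
    """Fitted 2D probabilistic map: two cluster regions + transition.

    ``normalization`` is the 2D whitening of the projected feature pair,
    fitted on the training events; the density and its ellipses live in
    that whitened map space.
    """

    projection: tuple[str, str]
    normalization: NormalizationModel    # 2D, over the projected pair
    density: ddft.DensityModel           # exactly 2 components
    normal_idx: int
    fall_idx: int
    sd_multiplier: float = SD_MULTIPLIER
    selected_K: int = 2
    curve: ddft.HamiltonianCurve | None = None
    boundary: ddft.ClusterBoundary | None = None

    def __post_init__(self) -> None:
        if self.density.K != 2:
            raise ParameterError("a fall map needs exactly 2 components")
        if self.normal_idx == self.fall_idx:
            raise ParameterError("normal and fall roles must be distinct")

    def _mahalanobis(self, points: np.ndarray, idx: int) -> np.ndarray:
        diff = np.atleast_2d(points) - self.density.means[idx]
        cf = cho_factor(self.density.covariances[idx])
        return np.sqrt(np.einsum("ij,ji->i", diff, cho_solve(cf, diff.T)))

    def project(self, features: np.ndarray) -> np.ndarray:
        """Map raw (x, y, z, speed) feature rows into map coordinates."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] == 2:      # already projected raw pair
            return self.normalization.apply(features)
        idx = projection_indices(self.projection)
        return self.normalization.apply(features[:, list(idx)])

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": "1.0",
            "kind": "fall_map",
            "projection": list(self.projection),
            "normalization": json.loads(self.normalization.to_json()),
            "density": self.density.to_dict(),
            "normal_idx": int(self.normal_idx),
            "fall_idx": int(self.fall_idx),
            "sd_multiplier": float(self.sd_multiplier),
            "selected_K": int(self.selected_K),
        })

    @classmethod
    def from_json(cls, text: str) -> "FallMap":
        d = json.loads(text)
        if d.get("kind") != "fall_map" or d.get("schema_version", "").split(".")[0] != "1":
            raise ConfigurationError("not a compatible fall-map file")
        return cls(projection=tuple(d["projection"]),
                   normalization=NormalizationModel.from_json(
                       json.dumps(d["normalization"])),
                   density=ddft.DensityModel.from_dict(d["density"]),
                   normal_idx=int(d["normal_idx"]),
                   fall_idx=int(d["fall_idx"]),
                   sd_multiplier=float(d["sd_multiplier"]),
                   selected_K=int(d["selected_K"]))


def assign_roles(density: ddft.DensityModel,
                 start_centroid: np.ndarray | None = None,
                 ) -> tuple[int, int]:
    """(normal_idx, fall_idx) from the intensity/scatter asymmetry.

    When ``start_centroid`` (the centroid of the training events' first
    samples) is available it decides: event streams begin in normal
    motion, so the component whose mean lies nearest is the normal one.
    This stays correct even when both clusters are nearly degenerate
    (e.g. noiseless data, where a terminal lying-at-rest cluster can be
    just as intense and tight as the normal one).  Without it the
    intensity/scatter asymmetry decides: normal motion shows the higher
    mixture density peak w / sqrt((2 pi)^d det C), falling the wider
    scatter.
    """
    if start_centroid is not None:
        dist = np.linalg.norm(density.means - np.asarray(start_centroid),
                              axis=1)
        normal_idx = int(np.argmin(dist))
    else:
        dets = np.array([np.linalg.det(c) for c in density.covariances])
        peaks = density.weights / np.sqrt((2 * np.pi) ** density.dim * dets)
        normal_idx = int(np.argmax(peaks))
    return normal_idx, 1 - normal_idx


def build_fall_map(training_features: np.ndarray,
                   projection: tuple[str, str] = DEFAULT_PROJECTION,
                   seed: int = 0, K_max: int = 6,
                   eps: float = ddft.SLOPE_EPS,
                   sd_multiplier: float = SD_MULTIPLIER,
                   compute_boundary: bool = True,
                   grid_resolution: int = ddft.GRID_RESOLUTION,
                   event_start_features: np.ndarray | None = None) -> FallMap:
    """Fit the 2D probabilistic map on raw training trajectory features.

    Projects the (x, y, z, speed) rows onto the map pair, fits the 2D
    whitening on them, then runs the Hamiltonian-curve cluster-number
    selection on the whitened points (two clusters expected); if a
    different K is selected, the fit proceeds with the two most-weighted
    components after a warning.  ``event_start_features`` (raw first
    samples of the training events) anchor the normal cluster role.
    """
    feats = np.asarray(training_features, dtype=float)
    if feats.shape[0] <= K_max:
        raise ParameterError("not enough training points for a fall map")
    idx = projection_indices(projection)
    raw_pair = feats[:, list(idx)] if feats.shape[1] != 2 else feats
    norm = fit_normalization(raw_pair, feature_names=projection)
    pts = norm.apply(raw_pair)

    curve = ddft.hamiltonian_curve(pts, K_max=K_max, seed=seed, eps=eps)
    k_star = curve.selected_K
    model = ddft.fit_density(pts, k_star, seed)
    if k_star != 2:
        warnings.warn(f"selected cluster number {k_star} != 2; "
                      "proceeding with the 2 most-weighted components",
                      stacklevel=2)
        top = np.argsort(model.weights)[-2:]
        w = model.weights[top]
        model = ddft.DensityModel(K=2, weights=w / w.sum(),
                                  means=model.means[top],
                                  covariances=model.covariances[top],
                                  fit_seed=seed,
                                  log_likelihood=model.log_likelihood)
    start_centroid = None
    if event_start_features is not None:
        starts = np.atleast_2d(np.asarray(event_start_features, dtype=float))
        if starts.shape[1] != 2:
            starts = starts[:, list(idx)]
        start_centroid = norm.apply(starts).mean(axis=0)
    normal_idx, fall_idx = assign_roles(model, start_centroid)
    log.info("fall map: K*=%d, roles normal=%d fall=%d", k_star,
             normal_idx, fall_idx)

    boundary = None
    if compute_boundary:
        boundary = ddft.lagrangian_boundaries(model, pts,
                                              resolution=grid_resolution)
    return FallMap(projection=projection, normalization=norm, density=model,
                   normal_idx=normal_idx, fall_idx=fall_idx,
                   sd_multiplier=sd_multiplier, selected_K=k_star,
                   curve=curve, boundary=boundary)


def classify_points(fall_map: FallMap, points_2d: np.ndarray) -> np.ndarray:
    """State per projected point: normal / transition / fall.

    Mahalanobis distance to the normal component <= the SD multiplier
    wins first, then the fall component, else transition; the priority
    order breaks measure-zero boundary ties deterministically.
    """
    pts = np.atleast_2d(np.asarray(points_2d, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ParameterError("points must be finite")
    d_normal = fall_map._mahalanobis(pts, fall_map.normal_idx)
    d_fall = fall_map._mahalanobis(pts, fall_map.fall_idx)
    out = np.full(pts.shape[0], STATE_TRANSITION, dtype=object)
    out[d_fall <= fall_map.sd_multiplier] = STATE_FALL
    out[d_normal <= fall_map.sd_multiplier] = STATE_NORMAL
    return out.astype(str)


def classify_features(fall_map: FallMap, features: np.ndarray) -> np.ndarray:
    """Classify raw feature rows (projects into map space, then classifies)."""
    return classify_points(fall_map, fall_map.project(features))


@dataclass(frozen=True)
class AlarmState:
    """Alarm finite-state machine: idle -> alarming -> fall_latched -> off."""

    status: str = "idle"
    alarm_start_t: float | None = None
    latch_t: float | None = None
    last_t: float | None = None
    shutoff_delay: float = SHUTOFF_DELAY_S


def step_alarm(state: AlarmState, classified: str, t: float) -> AlarmState:
    """Advance the alarm machine by one classified sample.

    Transition or fall starts the alarm; the first fall latches it and
    the machine turns off ``shutoff_delay`` seconds after the latch.
    Normal motion silences an unlatched alarm.
    """
    if state.last_t is not None and t <= state.last_t:
        raise ParameterError("time must be strictly increasing")
    state = replace(state, last_t=t)
    if state.status == "off":
        return state
    if state.status == "fall_latched":
        if t >= state.latch_t + state.shutoff_delay:
            return replace(state, status="off")
        return state
    if classified == STATE_FALL:
        start = state.alarm_start_t if state.alarm_start_t is not None else t
        return replace(state, status="fall_latched", alarm_start_t=start,
                       latch_t=t)
    if classified == STATE_TRANSITION:
        start = state.alarm_start_t if state.alarm_start_t is not None else t
        return replace(state, status="alarming", alarm_start_t=start)
    # normal: an unlatched alarm stops
    return replace(state, status="idle", alarm_start_t=None)


def run_alarm(times: np.ndarray, classified: np.ndarray,
              shutoff_delay: float = SHUTOFF_DELAY_S,
              ) -> tuple[list[str], AlarmState]:
    """Run the alarm machine over one event stream."""
    state = AlarmState(shutoff_delay=shutoff_delay)
    trace = []
    for t, c in zip(times, classified):
        state = step_alarm(state, str(c), float(t))
        trace.append(state.status)
    return trace, state


@dataclass
class LeadTimeReport:
    """Alarm lead times: seconds from alarm start to true fall onset."""

    per_event: list[float]
    mean: float | None
    n_late: int
    n_no_alarm: int


def alarm_lead_time(event_results: list[dict]) -> LeadTimeReport:
    """Lead-time summary over events.

    Each entry needs ``times``, ``classified`` (predicted states) and
    ``fall_onset_t`` (ground truth).  Events whose alarm follows the
    fall are excluded from the mean and counted as late alarms.
    """
    leads, n_late, n_none = [], 0, 0
    for ev in event_results:
        _, final = run_alarm(ev["times"], ev["classified"],
                             ev.get("shutoff_delay", SHUTOFF_DELAY_S))
        onset = ev.get("fall_onset_t")
        if final.alarm_start_t is None or onset is None:
            n_none += 1
            continue
        lead = onset - final.alarm_start_t
        if lead >= 0:
            leads.append(float(lead))
        else:
            n_late += 1
    mean = float(np.mean(leads)) if leads else None
    return LeadTimeReport(per_event=leads, mean=mean, n_late=n_late,
                          n_no_alarm=n_none)
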