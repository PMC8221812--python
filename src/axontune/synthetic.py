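"""Synthetic sessions with known ground truth.

Generates drifting-grating stimulus protocols, tuned ROI responses,
optogenetic suppression effects, visuo-motor (running-speed / optic-flow)
sessions and toy-atlas cell maps.  Every generator takes an explicit seed
and is bit-reproducible; ground truth is returned alongside the data so
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

# Stimulus grid used throughout: octave-spaced SFs (cycles/degree) and TFs
# (Hz), 8 drift directions; the opto variant drops oblique orientations and
# crosses the remaining 100 gratings with a laser on/off flag.
DEFAULT_SFS = (0.02, 0.04, 0.08, 0.16, 0.32)
DEFAULT_TFS = (0.5, 1.0, 2.0, 4.0, 8.0)
DEFAULT_DIRECTIONS = tuple(float(d) for d in range(0, 360, 45))
OPTO_DIRECTIONS = (0.0, 90.0, 180.0, 270.0)

STATIC_DURATION = 1.2      # s of static grating before drift
DRIFT_DURATION = 2.15      # s of drift (standard protocol)
DRIFT_DURATION_OPTO = 2.3  # s of drift in the laser protocol
LASER_DELAY = 0.5          # laser onset after static-grating onset
LASER_DURATION = 2.0
GRAY_DURATION_OPTO = 0.5   # gray screen between laser trials


@dataclass
class StimulusTrial:
    """One grating presentation."""

    sf: float                 # cycles/degree
    tf: float                 # Hz
    direction: float          # degrees in [0, 360)
    laser: int                # 0/1
    static_onset: float       # s
    drift_onset: float        # s
    drift_offset: float       # s
    laser_onset: float | None = None
    laser_offset: float | None = None
    repeat_index: int = 0

    def __post_init__(self) -> None:
        if self.sf <= 0 or self.tf <= 0:
            raise ValueError("sf and tf must be positive")
        if self.drift_onset <= self.static_onset:
            raise ValueError("drift must start after the static grating")
        if self.laser and (self.laser_offset is None or self.laser_onset is None
                           or self.laser_offset <= self.laser_onset):
            raise ValueError("laser trials need laser_offset > laser_onset")


@dataclass
class GroundTruthTuning:
    """Generative tuning of one synthetic ROI.

    The expected trial response is

        r = baseline + gain * exp(-(log2 sf - sf_pref)^2 / (2 sf_sigma^2))
                            * exp(-(log2 tf - tf_pref)^2 / (2 tf_sigma^2))
                            * exp(dir_kappa * (cos(dir - dir_pref) - 1))

    scaled by ``laser_factor`` on laser trials, plus N(0, noise_sd) trial
    noise.  ``sf_pref``/``tf_pref`` live in log2 units of the stimulus
    values (octaves).
    """

    sf_pref: float
    tf_pref: float
    sf_sigma: float = 1.0
    tf_sigma: float = 1.0
    dir_pref: float = 0.0
    dir_kappa: float = 1.0
    gain: float = 1.0
    baseline: float = 0.1
    laser_factor: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.dir_kappa < 0 or self.gain < 0 or self.baseline < 0:
            raise ValueError("dir_kappa, gain and baseline must be >= 0")
        if not 0.0 <= self.laser_factor <= 1.0:
            raise ValueError("laser_factor must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def expected_response(self, sf: float, tf: float, direction: float,
                          laser: int = 0) -> float:
        shape = (
            np.exp(-(np.log2(sf) - self.sf_pref) ** 2 / (2 * self.sf_sigma ** 2))
            * np.exp(-(np.log2(tf) - self.tf_pref) ** 2 / (2 * self.tf_sigma ** 2))
            * np.exp(self.dir_kappa * (np.cos(np.deg2rad(direction - self.dir_pref)) - 1.0))
        )
        r = self.baseline + self.gain * shape
        if laser:
            r = self.laser_factor * r
        return float(r)


@dataclass
class RoiRecording:
    """Per-ROI activity traces at a fixed frame rate."""

    dff: np.ndarray
    rate: np.ndarray
    frame_rate: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    roi_id: int = 0

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.rate.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.dff) == len(self.rate) == len(self.valid)):
            raise ValueError("dff, rate and valid must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.rate)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class BehaviorSession:
    """Per-frame behavioral time series of one session."""

    frame_rate: float
    running_speed: np.ndarray   # cm/s
    optic_flow_speed: np.ndarray  # cm/s
    reward_times: np.ndarray | None = None
    couplings: list | None = None  # ground-truth (w_rs, w_of, lag_frames, noise_sd)

    def __post_init__(self) -> None:
        self.running_speed = np.asarray(self.running_speed, dtype=float)
        self.optic_flow_speed = np.asarray(self.optic_flow_speed, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if len(self.running_speed) != len(self.optic_flow_speed):
            raise ValueError("running and optic-flow series must have equal length")


def make_grating_protocol(
    sfs: Sequence[float] = DEFAULT_SFS,
    tfs: Sequence[float] = DEFAULT_TFS,
    directions: Sequence[float] = DEFAULT_DIRECTIONS,
    laser_conditions: Sequence[int] = (0,),
    n_repeats: int = 6,
    static_duration: float = STATIC_DURATION,
    drift_duration: float = DRIFT_DURATION,
    gray_duration: float = 0.0,
    laser_delay: float = LASER_DELAY,
    laser_duration: float = LASER_DURATION,
    seed: int = 0,
) -> list[StimulusTrial]:
    """Full factorial grating protocol, shuffled within each repeat block.

    The trial count is |sfs|*|tfs|*|directions|*|laser_conditions|*n_repeats;
    with the default grids this gives the classic 200-condition set (5 SF x
    5 TF x 8 directions, or 5 x 5 x 4 directions x 2 laser states).
    """
    if not (len(sfs) and len(tfs) and len(directions) and len(laser_conditions)):
        raise ValueError("all stimulus parameter lists must be non-empty")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if static_duration <= 0 or drift_duration <= 0 or gray_duration < 0:
        raise ValueError("durations must be positive (gray may be zero)")

    conditions = [
        (sf, tf, d, int(l))
        for sf in sfs for tf in tfs for d in directions for l in laser_conditions
    ]
    rng = np.random.default_rng(seed)
    trials: list[StimulusTrial] = []
    t = 0.0
    for rep in range(n_repeats):
        order = rng.permutation(len(conditions))
        for idx in order:
            sf, tf, d, laser = conditions[idx]
            static_onset = t
            drift_onset = static_onset + static_duration
            drift_offset = drift_onset + drift_duration
            laser_onset = laser_offset = None
            if laser:
                laser_onset = static_onset + laser_delay
                laser_offset = laser_onset + laser_duration
            trials.append(StimulusTrial(
                sf=sf, tf=tf, direction=d, laser=laser,
                static_onset=static_onset, drift_onset=drift_onset,
                drift_offset=drift_offset, laser_onset=laser_onset,
                laser_offset=laser_offset, repeat_index=rep,
            ))
            t = drift_offset + gray_duration
    return trials


def make_opto_protocol(n_repeats: int = 6, seed: int = 0) -> list[StimulusTrial]:
    """Laser-interleaved protocol: 4 directions, on/off laser, 2.3 s drift."""
    return make_grating_protocol(
        directions=OPTO_DIRECTIONS, laser_conditions=(0, 1),
        n_repeats=n_repeats, drift_duration=DRIFT_DURATION_OPTO,
        gray_duration=GRAY_DURATION_OPTO, seed=seed,
    )


def simulate_tuned_responses(
    protocol: Sequence[StimulusTrial],
    tunings: Sequence[GroundTruthTuning],
    frame_rate: float = 30.0,
    run_speed: float = 5.0,
    frame_noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[list[RoiRecording], pd.DataFrame]:
    """Simulate trial responses and frame traces for a set of tuned ROIs.

    Returns one :class:`RoiRecording` per tuning plus a tidy trial-response
    table (roi, trial, sf, tf, direction, laser, run_speed, response).  The
    trial response is the generative mean plus N(0, noise_sd) noise; the
    frame trace carries that response as a boxcar over the drift window
    embedded in baseline noise, so window-averaged extraction recovers it.
    """
    if not tunings:
        raise ValueError("need at least one ROI tuning")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    protocol = list(protocol)
    t_end = max(tr.drift_offset for tr in protocol) + 1.0
    n_frames = int(np.ceil(t_end * frame_rate))
    if any(int(tr.drift_onset * frame_rate) >= n_frames for tr in protocol):
        raise ValueError("frame rate inconsistent with trial timings")

    master = np.random.default_rng(seed)
    roi_seeds = master.integers(0, 2 ** 31 - 1, size=len(tunings))
    recordings: list[RoiRecording] = []
    rows = []
    for roi, (tuning, roi_seed) in enumerate(zip(tunings, roi_seeds)):
        rng = np.random.default_rng(roi_seed)
        rate = tuning.baseline + rng.normal(0.0, frame_noise_sd, size=n_frames)
        for i, tr in enumerate(protocol):
            mean = tuning.expected_response(tr.sf, tr.tf, tr.direction, tr.laser)
            resp = mean + rng.normal(0.0, tuning.noise_sd)
            a = int(np.round(tr.drift_onset * frame_rate))
            b = int(np.round(tr.drift_offset * frame_rate))
            rate[a:b] += resp - tuning.baseline
            rows.append((roi, i, tr.sf, tr.tf, tr.direction, tr.laser,
                         run_speed, resp))
        recordings.append(RoiRecording(dff=rate.copy(), rate=rate,
                                       frame_rate=frame_rate, roi_id=roi))
    table = pd.DataFrame(rows, columns=[
        "roi", "trial", "sf", "tf", "direction", "laser", "run_speed",
        "response"])
    return recordings, table


def _ou_process(n: int, dt: float, tau: float, mu: float, sigma: float,
                rng: np.random.Generator) -> np.ndarray:
    """Rectified, smoothed Ornstein-Uhlenbeck process (cm/s-like)."""
    x = np.empty(n)
    x[0] = mu
    stat_sd = sigma * np.sqrt(tau / 2.0)
    for i in range(1, n):
        x[i] = x[i - 1] + (mu - x[i - 1]) * dt / tau \
            + sigma * np.sqrt(dt) * rng.standard_normal()
    x = np.maximum(x, 0.0)
    # 0.5 s moving average gives realistic short-range autocorrelation
    w = max(1, int(round(0.5 / dt)))
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def simulate_visuomotor_session(
    duration: float = 600.0,
    frame_rate: float = 30.0,
    couplings: Sequence[tuple[float, float, int, float]] = ((1.0, 0.0, 0, 0.1),),
    rs_mean: float = 8.0,
    of_mean: float = 10.0,
    process_sigma: float = 6.0,
    process_tau: float = 2.0,
    seed: int = 0,
) -> tuple[BehaviorSession, list[RoiRecording]]:
    """Session with independent running-speed and optic-flow processes.

    Emulates the "uncoupled" (replay) condition: RS and OF are independent
    rectified OU processes smoothed over 0.5 s.  Each ROI is a lagged linear
    readout  act(t) = w_rs*RS(t-lag) + w_of*OF(t-lag) + noise  whose
    ground-truth coupling is stored on the returned session.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    n = int(round(duration * frame_rate))
    if n < 120:
        raise ValueError("session too short: need at least 120 frames")
    dt = 1.0 / frame_rate
    master = np.random.default_rng(seed)
    rs = _ou_process(n, dt, process_tau, rs_mean, process_sigma,
                     np.random.default_rng(master.integers(2 ** 31 - 1)))
    of = _ou_process(n, dt, process_tau, of_mean, process_sigma,
                     np.random.default_rng(master.integers(2 ** 31 - 1)))

    recordings = []
    for roi, (w_rs, w_of, lag, noise_sd) in enumerate(couplings):
        rng = np.random.default_rng(master.integers(2 ** 31 - 1))
        act = (w_rs * _shift(rs, int(lag)) + w_of * _shift(of, int(lag))
               + rng.normal(0.0, noise_sd, size=n))
        recordings.append(RoiRecording(dff=act.copy(), rate=act,
                                       frame_rate=frame_rate, roi_id=roi))
    session = BehaviorSession(frame_rate=frame_rate, running_speed=rs,
                              optic_flow_speed=of,
                              couplings=[tuple(c) for c in couplings])
    return session, recordings


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift so that out[t] = x[t - lag], edges held."""
    if lag == 0:
        return x.copy()
    out = np.empty_like(x)
    if lag > 0:
        out[lag:] = x[:-lag]
        out[:lag] = x[0]
    else:
        out[:lag] = x[-lag:]
        out[lag:] = x[-1]
    return out


# ---------------------------------------------------------------------------
# Toy atlas and cell maps

@dataclass
class AtlasVolume:
    """Labeled 3D volume with isotropic voxels and a region/layer lookup.

    ``meta`` maps integer label -> dict(region, layer, is_cortex,
    is_white_matter).  Axes are (x, y, z) with z = depth.
    """

    labels: np.ndarray
    voxel_size_um: float
    meta: dict[int, dict]

    def ids_for_region(self, region: str) -> list[int]:
        return [k for k, v in self.meta.items() if v["region"] == region]


CORTEX_LAYERS = ("1", "2/3", "4", "5", "6a", "6b")


def make_toy_atlas(shape: tuple[int, int, int] = (60, 40, 40),
                   voxel_size_um: float = 10.0,
                   layer_thickness_vox: int = 3,
                   wm_thickness_vox: int = 10) -> AtlasVolume:
    """Procedural slab atlas: two cortical areas (A|B split along x), six
    stacked layers in depth, white matter below, one subcortical block."""
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int32)
    meta: dict[int, dict] = {}
    next_id = 1
    for area_idx, area in enumerate(("A", "B")):
        x_sl = slice(0, nx // 2) if area_idx == 0 else slice(nx // 2, nx)
        for li, layer in enumerate(CORTEX_LAYERS):
            z_sl = slice(li * layer_thickness_vox, (li + 1) * layer_thickness_vox)
            labels[x_sl, :, z_sl] = next_id
            meta[next_id] = {"region": area, "layer": layer,
                             "is_cortex": True, "is_white_matter": False}
            next_id += 1
    z_cortex = len(CORTEX_LAYERS) * layer_thickness_vox
    labels[:, :, z_cortex:z_cortex + wm_thickness_vox] = next_id
    meta[next_id] = {"region": "wm", "layer": None, "is_cortex": False,
                     "is_white_matter": True}
    next_id += 1
    labels[:, :, z_cortex + wm_thickness_vox:] = next_id
    meta[next_id] = {"region": "SUB", "layer": None, "is_cortex": False,
                     "is_white_matter": False}
    return AtlasVolume(labels=labels, voxel_size_um=voxel_size_um, meta=meta)


def simulate_cell_map(atlas: AtlasVolume, region_fractions: dict[str, float],
                      n_cells: int, brain: str = "brain0",
                      seed: int = 0) -> pd.DataFrame:
    """Place cells uniformly within regions, multinomial across regions.

    Returns a CellTable DataFrame (x_um, y_um, z_um, region, layer, brain).
    """
    fracs = np.array(list(region_fractions.values()), dtype=float)
    regions = list(region_fractions.keys())
    if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0):
        raise ValueError("region fractions must be non-negative and sum to 1")
    for region in regions:
        if not atlas.ids_for_region(region):
            raise KeyError(f"region {region!r} absent from atlas")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, fracs)
    rows = []
    vs = atlas.voxel_size_um
    for region, count in zip(regions, counts):
        ids = atlas.ids_for_region(region)
        vox = np.argwhere(np.isin(atlas.labels, ids))
        picks = vox[rng.integers(0, len(vox), size=count)]
        offsets = rng.uniform(0.0, 1.0, size=(count, 3))
        xyz = (picks + offsets) * vs
        for (x, y, z), (vx, vy, vz) in zip(xyz, picks):
            label = int(atlas.labels[vx, vy, vz])
            rows.append((x, y, z, region, atlas.meta[label]["layer"], brain))
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "region",
                                     "layer", "brain"])
    return df


# ---------------------------------------------------------------------------
# External interfaces

TRIAL_CSV_COLUMNS = ["sf", "tf", "direction", "laser", "static_onset",
                     "drift_onset", "drift_offset", "laser_onset",
                     "laser_offset", "repeat"]


def protocol_to_frame(protocol: Sequence[StimulusTrial]) -> pd.DataFrame:
    rows = [(t.sf, t.tf, t.direction, t.laser, t.static_onset, t.drift_onset,
             t.drift_offset, t.laser_onset, t.laser_offset, t.repeat_index)
            for t in protocol]
    return pd.DataFrame(rows, columns=TRIAL_CSV_COLUMNS)


def protocol_from_frame(df: pd.DataFrame) -> list[StimulusTrial]:
    out = []
    for _, r in df.iterrows():
        laser_on = r["laser_onset"]
        laser_off = r["laser_offset"]
        out.append(StimulusTrial(
            sf=float(r["sf"]), tf=float(r["tf"]), direction=float(r["direction"]),
            laser=int(r["laser"]), static_onset=float(r["static_onset"]),
            drift_onset=float(r["drift_onset"]), drift_offset=float(r["drift_offset"]),
            laser_onset=None if pd.isna(laser_on) else float(laser_on),
            laser_offset=None if pd.isna(laser_off) else float(laser_off),
            repeat_index=int(r["repeat"])))
    return out


def save_session_h5(path, recordings: Sequence[RoiRecording],
                    behavior: BehaviorSession | None = None,
                    seed: int | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for rec in recordings:
            g = f.create_group(f"roi/{rec.roi_id}")
            g.create_dataset("dff", data=rec.dff)
            g.create_dataset("rate", data=rec.rate)
            g.create_dataset("valid", data=rec.valid.astype(np.uint8))
        if behavior is not None:
            b = f.create_group("behavior")
            b.create_dataset("rs", data=behavior.running_speed)
            b.create_dataset("of", data=behavior.optic_flow_speed)
        fr = behavior.frame_rate if behavior is not None else recordings[0].frame_rate
        f.attrs["frame_rate"] = fr
        if seed is not None:
            f.attrs["seed"] = seed


def load_session_h5(path) -> tuple[list[RoiRecording], BehaviorSession | None]:
    import h5py

    with h5py.File(path, "r") as f:
        fr = float(f.attrs["frame_rate"])
        recs = []
        for key in sorted(f["roi"], key=int):
            g = f[f"roi/{key}"]
            recs.append(RoiRecording(
                dff=g["dff"][:], rate=g["rate"][:], frame_rate=fr,
                valid=g["valid"][:].astype(bool), roi_id=int(key)))
        behavior = None
        if "behavior" in f:
            behavior = BehaviorSession(
                frame_rate=fr, running_speed=f["behavior/rs"][:],
                optic_flow_speed=f["behavior/of"][:])
    return recs, behavior


def ground_truth_to_json(path, tunings: Sequence[GroundTruthTuning]) -> None:
    with open(path, "w") as f:
        json.dump([asdict(t) for t in tunings], f, indent=1)
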