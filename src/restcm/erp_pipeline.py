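"""ERP analysis chain for the visual oddball paradigm.

Preprocessing (6 Hz zero-phase low-pass, decimation 500 -> 250 Hz), epoching
on [-200, 800) ms with pre-stimulus baseline correction and +/-75 uV artifact
rejection, condition averaging, P300 amplitude/latency at Cz/CPz/Pz, CM
trajectory and traveling velocity over [200, 800) ms, stage-resolved
statistics across references, and the lagged cross-condition velocity
correlation.

Stage windows (post-stimulus): S1 210-350 ms (anterior-to-posterior sweep),
S2 350-480 ms (parietal P300 plateau), S3 480-740 ms (return to frontal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .center_of_mass import cm_trajectory, traveling_velocity
from .montage import ElectrodeMontage, cm_montage
from .referencing import ScalpRecording
from .transforms import LowpassDecimate
from . import stats as _stats

__all__ = [
    "Epochs",
    "StageWindows",
    "ERPMeasures",
    "preprocess",
    "make_epochs",
    "average_erp",
    "p300_measures",
    "stage_statistics",
    "condition_correlation",
]


@dataclass(frozen=True)
class StageWindows:
    """Post-stimulus stage intervals in seconds."""

    S1: tuple[float, float] = (0.210, 0.350)
    S2: tuple[float, float] = (0.350, 0.480)
    S3: tuple[float, float] = (0.480, 0.740)

    def __post_init__(self) -> None:
        w = [self.S1, self.S2, self.S3]
        for a, b in w:
            if b <= a:
                raise ValueError("stage windows must be increasing intervals")
        for (_, b), (a2, _) in zip(w, w[1:]):
            if a2 < b - 1e-12:
                raise ValueError("stage windows must not overlap")

    def items(self):
        return (("S1", self.S1), ("S2", self.S2), ("S3", self.S3))


@dataclass
class Epochs:
    """Trials x channels x samples, with rejection bookkeeping."""

    data: np.ndarray
    labels: tuple[str, ...]
    sfreq: float
    conditions: np.ndarray          # (n_trials,) str
    tmin: float = -0.2
    rejected: np.ndarray = field(default=None)
    reject_reason: list = field(default_factory=list)
    reference: str = "infinity"

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.data), dtype=bool)

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq

    def retained(self, condition: str | None = None) -> np.ndarray:
        mask = ~self.rejected
        if condition is not None:
            mask &= self.conditions == condition
        return mask


def preprocess(rec: ScalpRecording, cutoff: float = 6.0, order: int = 4,
               decim: int = 2) -> ScalpRecording:
    """Zero-phase Butterworth low-pass then decimation by sample picking."""
    tr = LowpassDecimate(sfreq=rec.sfreq, cutoff=cutoff, order=order,
                         decim=decim).fit()
    out = rec.copy()
    out.data = tr.transform(rec.data.T).T
    out.sfreq = rec.sfreq / decim
    return out


def make_epochs(
    rec: ScalpRecording,
    events: pd.DataFrame,
    tmin: float = -0.2,
    tmax: float = 0.8,
    baseline: tuple[float, float] = (-0.2, 0.0),
    reject_uv: float | None = 75.0,
    reject_labels=None,
) -> Epochs:
    """Cut condition-labelled epochs on [tmin, tmax) around stimulus onsets.

    Per epoch and channel the mean over the baseline interval [b0, 0) is
    subtracted; epochs whose analysis channels exceed the rejection threshold
    (strictly, |v| > reject_uv) are flagged rejected.  Events too close to the
    recording edges are skipped with a log entry.
    """
    n_pre = int(round(-tmin * rec.sfreq))
    n_tot = int(round((tmax - tmin) * rec.sfreq))
    if reject_labels is None:
        reject_labels = [l for l in rec.labels
                         if l not in ("VEOG", "HEOG", "TP9", "TP10")]
    rj_idx = [rec.index(l) for l in reject_labels]
    b0 = int(round((baseline[0] - tmin) * rec.sfreq))
    b1 = int(round((baseline[1] - tmin) * rec.sfreq))

    data, conds, skipped = [], [], []
    for onset, cond in zip(events["onset_s"], events["condition"]):
        i0 = int(round(onset * rec.sfreq)) - n_pre
        if i0 < 0 or i0 + n_tot > rec.n_samples:
            skipped.append((float(onset), "outside recording"))
            continue
        ep = rec.data[:, i0:i0 + n_tot].copy()
        ep -= ep[:, b0:b1].mean(axis=1, keepdims=True)
        data.append(ep)
        conds.append(str(cond))
    if not data:
        raise ValueError("no events inside the recording")
    arr = np.stack(data)
    rejected = np.zeros(len(arr), dtype=bool)
    reasons = [None] * len(arr)
    if reject_uv is not None:
        peak = np.abs(arr[:, rj_idx, :]).max(axis=(1, 2))
        rejected = peak > reject_uv
        for i in np.flatnonzero(rejected):
            reasons[i] = f"amplitude {peak[i]:.1f} uV > {reject_uv:g} uV"
    ep = Epochs(data=arr, labels=rec.labels, sfreq=rec.sfreq,
                conditions=np.array(conds), tmin=tmin, rejected=rejected,
                reject_reason=reasons, reference=rec.reference)
    ep.skipped_events = skipped
    return ep


def concatenate_epochs(epochs_list) -> Epochs:
    first = epochs_list[0]
    for e in epochs_list[1:]:
        if e.labels != first.labels or e.sfreq != first.sfreq:
            raise ValueError("epochs are not compatible")
    return Epochs(
        data=np.concatenate([e.data for e in epochs_list]),
        labels=first.labels, sfreq=first.sfreq,
        conditions=np.concatenate([e.conditions for e in epochs_list]),
        tmin=first.tmin,
        rejected=np.concatenate([e.rejected for e in epochs_list]),
        reject_reason=sum([e.reject_reason for e in epochs_list], []),
        reference=first.reference,
    )


def average_erp(ep: Epochs, condition: str) -> ScalpRecording:
    """Sample-wise mean over retained epochs of one condition."""
    mask = ep.retained(condition)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no retained epochs for condition {condition!r}")
    return ScalpRecording(
        data=ep.data[mask].mean(axis=0), labels=ep.labels, sfreq=ep.sfreq,
        reference=ep.reference, tmin=ep.tmin,
        meta={"n_averaged": n, "condition": condition},
    )


@dataclass(frozen=True)
class ERPMeasures:
    p300_amplitude: float        # uV, mean of the three electrode peaks
    p300_latency: float | None   # s, None when the signal is flat in-window
    per_electrode: dict


def p300_measures(erp: ScalpRecording, window: tuple[float, float] = (0.25, 0.50),
                  electrodes=("Cz", "CPz", "Pz")) -> ERPMeasures:
    """Positive-peak amplitude and latency, averaged over Cz/CPz/Pz."""
    times = erp.times
    sel = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not np.any(sel):
        raise ValueError("search window outside the ERP")
    amps, lats, per = [], [], {}
    for lab in electrodes:
        x = erp.data[erp.index(lab)][sel]
        i = int(np.argmax(x))
        amp = float(x[i])
        lat = None if np.ptp(x) == 0 else float(times[sel][i])
        per[lab] = {"amplitude": amp, "latency": lat}
        amps.append(amp)
        if lat is not None:
            lats.append(lat)
    latency = float(np.mean(lats)) if len(lats) == len(electrodes) else None
    return ERPMeasures(p300_amplitude=float(np.mean(amps)),
                       p300_latency=latency, per_electrode=per)


# ---------------------------------------------------------------------------
# stage-level statistics


def stage_table(results: pd.DataFrame, stages: StageWindows | None = None) -> pd.DataFrame:
    """Per subject/reference/condition/stage means of CM coordinates and speed.

    ``results`` is a long per-sample table with columns subject, reference,
    condition, time, X, Y, speed (speed may be NaN at undefined steps).
    """
    stages = stages or StageWindows()
    out = []
    for name, (a, b) in stages.items():
        sel = results[(results.time >= a - 1e-9) & (results.time <= b + 1e-9)]
        g = sel.groupby(["subject", "reference", "condition"], observed=True)
        agg = g.agg(mean_x=("X", "mean"), mean_y=("Y", "mean"),
                    mean_speed=("speed", "mean")).reset_index()
        agg["stage"] = name
        out.append(agg)
    return pd.concat(out, ignore_index=True)


def stage_statistics(results: pd.DataFrame, stages: StageWindows | None = None,
                     condition: str = "target",
                     measures=("mean_y", "mean_speed")) -> dict:
    """Reference-effect tests per stage on subject-level stage means.

    For each stage and measure, a one-way repeated-measures ANOVA across
    references (subjects as the repeated factor) with Greenhouse-Geisser
    correction, followed by Tukey HSD with the within-subject error term.
    Returns {'table': stage table, 'tests': {stage: {measure: {...}}}}.
    """
    tab = stage_table(results, stages)
    refs = sorted(tab.reference.unique())
    if len(refs) < 2:
        raise ValueError("need at least two references to compare")
    tests: dict = {}
    for stage in ("S1", "S2", "S3"):
        tests[stage] = {}
        sub = tab[(tab.stage == stage) & (tab.condition == condition)]
        wide_check = sub.pivot(index="subject", columns="reference", values=measures[0])
        if wide_check.isna().any().any():
            raise ValueError("unbalanced design: missing subject/reference cells")
        for meas in measures:
            wide = sub.pivot(index="subject", columns="reference", values=meas)
            wide = wide[refs]
            anova = _stats.rm_anova_gg(wide.to_numpy())
            tukey = _stats.tukey_hsd(wide.to_numpy(), names=refs)
            tests[stage][meas] = {"anova": anova, "tukey": tukey}
    return {"table": tab, "tests": tests}


def condition_correlation(
    speed_target: np.ndarray,
    speed_standard: np.ndarray,
    times: np.ndarray,
    stages: StageWindows | None = None,
    s1_lag: float = 0.040,
) -> dict:
    """Cross-condition correlation of group-mean CM speeds per stage.

    S1 pairs the target curve on [250, 350] ms with the standard curve on
    [210, 310] ms (a 40 ms lag); S2 and S3 pair identical windows (endpoints
    inclusive).  Returns {stage: CorrFit}.
    """
    stages = stages or StageWindows()
    times = np.asarray(times)
    dt = float(np.median(np.diff(times)))

    def pick(curve, a, b):
        # nearest-sample endpoints, inclusive (e.g. 26 samples for a 100 ms
        # window at 250 Hz)
        i0 = int(np.floor((a - times[0]) / dt + 0.5))
        i1 = int(np.floor((b - times[0]) / dt + 0.5))
        return np.asarray(curve)[max(i0, 0):i1 + 1]

    out = {}
    a1, b1 = 0.250, 0.350
    x = pick(speed_target, a1, b1)
    y = pick(speed_standard, a1 - s1_lag, b1 - s1_lag)
    out["S1"] = _stats.pearson_corr_fit(x[: len(y)], y[: len(x)])
    for name, (a, b) in (("S2", stages.S2), ("S3", stages.S3)):
        x = pick(speed_target, a, b)
        y = pick(speed_standard, a, b)
        out[name] = _stats.pearson_corr_fit(x, y)
    return out


# ---------------------------------------------------------------------------
# subject-level driver


def run_oddball_analysis(
    cohort,
    references=("REST", "AR", "LM"),
    grid=None,
    window: tuple[float, float] = (0.2, 0.8),
    dim: int = 2,
    scale_radius: float = 0.10,
    sv_cutoff: float = 1e-4,
    subjects=None,
):
    """Full multi-subject reference comparison on an oddball cohort.

    Per subject and reference: re-reference the continuous recordings
    (REST via the transfer matrix built for the recorded reference),
    low-pass/decimate, epoch with baseline correction and artifact rejection,
    average per condition, and extract P300 measures plus the CM trajectory
    and traveling velocity on [200, 800) ms.

    Returns a dict with ``samples`` (long per-sample table: subject,
    reference, condition, time, X, Y, speed), ``measures`` (per subject/
    reference/condition P300 amplitude and latency, retained counts) and
    ``group_speed`` ({(reference, condition): mean speed across subjects},
    plus ``times``).
    """
    from .head_model import build_dipole_grid, leadfield_infinity
    from .referencing import apply_common_reference, apply_rest, rest_operator_for

    montage = cohort.montage
    scalp_labels = [l for l in montage.labels if l not in montage.non_scalp]
    scalp_montage = montage.subset(scalp_labels)
    model = cohort.model
    grid = grid or build_dipole_grid()
    cmm = cm_montage(scalp_montage)

    rest_op = None
    recorded_ref = None
    if "REST" in references:
        lf = leadfield_infinity(model, scalp_montage, grid)
        recorded_ref = f"recorded:{cohort.cfg.recorded_reference}"
        rest_op = rest_operator_for(lf, recorded_ref, sv_cutoff=sv_cutoff)

    sample_rows, meas_rows = [], []
    speed_curves: dict = {}
    subjects = range(cohort.cfg.n_subjects) if subjects is None else subjects
    for i in subjects:
        sub = cohort.subject(i)
        for ref in references:
            eps = []
            for rec, ev in zip(sub.sessions, sub.events):
                srec = rec.pick(scalp_labels)
                if ref == "REST":
                    srec.reference = recorded_ref
                    srec = apply_rest(srec, rest_op)
                else:
                    srec = apply_common_reference(srec, ref)
                srec = preprocess(srec)
                eps.append(make_epochs(srec, ev,
                                       reject_labels=list(cmm.labels)))
            ep = concatenate_epochs(eps)
            for cond in ("target", "standard"):
                erp = average_erp(ep, cond)
                traj, vel, meas = analyze_average_erp(
                    erp, scalp_montage, window=window, dim=dim,
                    scale_radius=scale_radius)
                speed = np.concatenate([[np.nan], vel.speed])
                sample_rows.append(pd.DataFrame({
                    "subject": i, "reference": ref, "condition": cond,
                    "time": traj.times, "X": traj.coords[:, 0],
                    "Y": traj.coords[:, 1], "speed": speed,
                }))
                speed_curves.setdefault((ref, cond), []).append(speed)
                meas_rows.append({
                    "subject": i, "reference": ref, "condition": cond,
                    "p300_amplitude": meas.p300_amplitude,
                    "p300_latency": meas.p300_latency,
                    "n_averaged": erp.meta["n_averaged"],
                    "n_total": int((ep.conditions == cond).sum()),
                })

    samples = pd.concat(sample_rows, ignore_index=True)
    measures = pd.DataFrame(meas_rows)
    times = samples[(samples.subject == samples.subject.iloc[0])
                    & (samples.reference == references[0])
                    & (samples.condition == "target")]["time"].to_numpy()
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN first step
        group_speed = {key: np.nanmean(np.stack(v), axis=0)
                       for key, v in speed_curves.items()}
    return {"samples": samples, "measures": measures,
            "group_speed": group_speed, "times": times}


def analyze_average_erp(
    erp: ScalpRecording,
    montage: ElectrodeMontage,
    window: tuple[float, float] = (0.2, 0.8),
    dim: int = 2,
    scale_radius: float = 0.10,
):
    """CM trajectory, velocity and P300 measures of one averaged ERP."""
    cmm = cm_montage(montage)
    traj = cm_trajectory(erp, cmm, window=window, dim=dim)
    vel = traveling_velocity(traj, scale_radius=scale_radius)
    meas = p300_measures(erp)
    return traj, vel, meas
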