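"""Seedable synthetic visual-oddball ERP cohort.

Emulates the study conditions the analysis assumes: 12 subjects, three
sessions of 150 trials (exact 30 target / 120 standard split), 500 Hz, a
63-channel cap recorded against FCz.  Event-related components are lumped
equivalent dipoles on the midline driven by damped-Gaussian waveforms:

* P200  — frontal, 200 ms, both conditions;
* P250  — fronto-central, 250 ms, larger for the standard stimulus;
* P300  — midline parietal, 360 ms, target only, ~10 uV at the scalp peak;
* LFP   — late frontal positivity, 600 ms, both conditions (the recovery
  stage: without late frontal positive activity the posterior-to-frontal
  return of the CM trajectory the analysis looks for cannot occur).

Across subjects, component amplitudes are jittered lognormally (sigma 0.2)
and latencies normally (sigma 20 ms).  Background activity comes from 20
random deep dipoles with low-pass-filtered Gaussian time courses (spatially
correlated, like real EEG) plus white sensor noise; a small fraction of
trials receives a large slow frontal deflection so the +/-75 uV artifact
rejection has something to reject.  Everything is reproducible bit-for-bit
from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .head_model import HeadModel, _gain_matrix
from .montage import ElectrodeMontage, ideal_position, standard_cap63, write_sfp
from .referencing import ScalpRecording
from .simulation_study import damped_gaussian

__all__ = ["Component", "SynthConfig", "SynthCohort", "generate_cohort",
           "write_fixture"]


@dataclass(frozen=True)
class Component:
    """A lumped equivalent-dipole ERP component."""

    name: str
    position: tuple[float, float, float]
    peak_s: float
    width_s: float                       # Gaussian envelope time constant tau
    amplitude_uv: dict                   # condition -> peak scalp amplitude, uV
    cal_label: str | None = None         # electrode the amplitude refers to
                                         # (None: the map's peak scalp electrode)

    def waveform(self, dt: float, k: int, peak_shift: float = 0.0):
        """Unit-peak damped-Gaussian bump sampled on k points from t = 0."""
        f = 1.0 / (8.0 * self.width_s)   # slow carrier: no sign flip in-envelope
        gamma = 2.0 * np.pi * f * self.width_s
        return damped_gaussian(t0=self.peak_s + peak_shift, f=f, gamma=gamma,
                               alpha=0.0, dt=dt, k=k).h


DEFAULT_COMPONENTS = (
    Component("P200", (0.0, 0.45, 0.45), 0.20, 0.035,
              {"target": 6.0, "standard": 6.0}),
    Component("P250", (0.0, 0.20, 0.60), 0.25, 0.045,
              {"target": 4.0, "standard": 7.0}),
    Component("P300", (0.0, -0.15, 0.30), 0.36, 0.090,
              {"target": 10.0, "standard": 0.0}, cal_label="Pz"),
    Component("LFP", (0.0, 0.45, 0.45), 0.60, 0.110,
              {"target": 4.0, "standard": 4.0}),
)


@dataclass(frozen=True)
class SynthConfig:
    n_subjects: int = 12
    n_sessions: int = 3
    trials_per_session: int = 150
    target_fraction: float = 0.20        # exact split: 30 target / 120 standard
    sfreq: float = 500.0
    components: tuple[Component, ...] = DEFAULT_COMPONENTS
    amp_jitter_sigma: float = 0.2        # lognormal, per subject x component
    latency_jitter_sigma: float = 0.020  # s, per subject x component
    n_bg_dipoles: int = 20
    bg_rms_uv: float = 7.0               # sensor-level RMS of background activity
    bg_cutoff_hz: float = 20.0
    sensor_rms_uv: float = 3.0           # white sensor noise RMS
    artifact_prob: float = 0.08
    artifact_amp_uv: float = 150.0
    cue_s: float = 0.25
    fixation_s: float = 0.50
    stimulus_s: float = 0.50
    lead_in_s: float = 1.0
    tail_s: float = 1.5
    recorded_reference: str = "FCz"
    seed: int = 2017

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fraction < 1.0:
            raise ValueError("target fraction must be in (0, 1)")
        n_target = self.target_fraction * self.trials_per_session
        if abs(n_target - round(n_target)) > 1e-9:
            raise ValueError("target fraction must give an exact per-session split")

    @property
    def n_targets_per_session(self) -> int:
        return int(round(self.target_fraction * self.trials_per_session))

    @property
    def trial_len_s(self) -> float:
        return self.cue_s + self.fixation_s + self.stimulus_s

    @property
    def stimulus_offset_s(self) -> float:
        return self.cue_s + self.fixation_s


@dataclass
class SubjectData:
    subject: int
    sessions: list                        # list[ScalpRecording], FCz-referenced
    events: list                          # list[pd.DataFrame] (onset_s, condition)
    ground_truth: dict


FRONTAL_ARTIFACT_CHANNELS = ("Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
                             "VEOG", "HEOG")


class SynthCohort:
    """Lazily materialized multi-subject cohort.

    Subject recordings are generated on demand (deterministically from the
    config seed) to keep memory bounded; ``subject(i)`` always returns
    bit-identical data for the same (config, seed).
    """

    def __init__(self, cfg: SynthConfig, montage: ElectrodeMontage | None = None,
                 model: HeadModel | None = None):
        self.cfg = cfg
        self.montage = montage or standard_cap63()
        self.model = model or HeadModel()
        for comp in cfg.components:
            if np.linalg.norm(comp.position) >= self.model.brain_radius:
                raise ValueError(
                    f"component {comp.name!r} lies outside the source space")
        # electrode set for generation: montage channels + the recording reference
        ref = cfg.recorded_reference
        self._gen_labels = self.montage.labels + (ref,)
        gen_pos = np.vstack([self.montage.positions, ideal_position(ref)])
        comp_pos = np.array([c.position for c in cfg.components])
        gain = _gain_matrix(self.model, gen_pos, comp_pos)          # (E+1, 3C)
        # radial unit moments; dipole at the origin would be degenerate
        radial = comp_pos / np.linalg.norm(comp_pos, axis=1, keepdims=True)
        cols = np.stack([gain[:, 3 * i:3 * i + 3] @ radial[i]
                         for i in range(len(comp_pos))], axis=1)    # (E+1, C)
        # scale each component map to unit amplitude at its calibration
        # electrode (default: the map's peak scalp electrode)
        scalp = np.array([l not in self.montage.non_scalp
                          for l in self._gen_labels])
        peaks = np.array([
            cols[self._gen_labels.index(c.cal_label), ci] if c.cal_label
            else cols[scalp, ci].max()
            for ci, c in enumerate(cfg.components)])
        if np.any(peaks <= 0):
            raise ValueError("component map has no positive calibration peak")
        self._comp_maps = cols / peaks[None, :]                     # peak = 1 uV
        self._sub_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)

    # -- per-subject generation -------------------------------------------

    def subject(self, i: int) -> SubjectData:
        cfg = self.cfg
        if not 0 <= i < cfg.n_subjects:
            raise IndexError(i)
        rng = np.random.default_rng(self._sub_seeds[i])
        ncomp = len(cfg.components)
        amp_mult = np.exp(rng.normal(0.0, cfg.amp_jitter_sigma, size=ncomp))
        lat_shift = rng.normal(0.0, cfg.latency_jitter_sigma, size=ncomp)
        sessions, events = [], []
        for s in range(cfg.n_sessions):
            rec, ev = self._session(rng, amp_mult, lat_shift)
            sessions.append(rec)
            events.append(ev)
        gt = {
            "subject": i,
            "amplitude_multipliers": {c.name: float(m) for c, m in
                                      zip(cfg.components, amp_mult)},
            "latency_shifts_s": {c.name: float(d) for c, d in
                                 zip(cfg.components, lat_shift)},
            "components": [dataclasses.asdict(c) for c in cfg.components],
        }
        return SubjectData(subject=i, sessions=sessions, events=events,
                           ground_truth=gt)

    def __iter__(self):
        return (self.subject(i) for i in range(self.cfg.n_subjects))

    def _session(self, rng, amp_mult, lat_shift):
        cfg = self.cfg
        dt = 1.0 / cfg.sfreq
        n_trials = cfg.trials_per_session
        dur = cfg.lead_in_s + n_trials * cfg.trial_len_s + cfg.tail_s
        T = int(round(dur * cfg.sfreq))
        E = len(self._gen_labels)
        data = np.zeros((E, T))

        # exact condition split, shuffled
        conds = np.array(["target"] * cfg.n_targets_per_session
                         + ["standard"] * (n_trials - cfg.n_targets_per_session))
        conds = conds[rng.permutation(n_trials)]
        onsets = (cfg.lead_in_s + np.arange(n_trials) * cfg.trial_len_s
                  + cfg.stimulus_offset_s)

        # evoked components
        k_ep = int(round(1.2 * cfg.sfreq))       # 1.2 s of post-onset waveform
        waves = np.stack([
            amp_mult[c] * comp.waveform(dt, k_ep, peak_shift=lat_shift[c])
            for c, comp in enumerate(cfg.components)])              # (C, k)
        amp_by_cond = {
            cond: np.array([comp.amplitude_uv.get(cond, 0.0)
                            for comp in cfg.components])
            for cond in ("target", "standard")}
        for onset, cond in zip(onsets, conds):
            i0 = int(round(onset * cfg.sfreq))
            amps = amp_by_cond[cond]
            data[:, i0:i0 + k_ep] += self._comp_maps @ (amps[:, None] * waves)

        # spatially correlated background: deep random dipoles
        if cfg.n_bg_dipoles > 0 and cfg.bg_rms_uv > 0:
            pos = rng.uniform(-1.0, 1.0, size=(4 * cfg.n_bg_dipoles, 3))
            pos = pos[np.linalg.norm(pos, axis=1) < 0.6][: cfg.n_bg_dipoles]
            while len(pos) < cfg.n_bg_dipoles:   # pragma: no cover (unlikely)
                extra = rng.uniform(-1.0, 1.0, size=(cfg.n_bg_dipoles, 3))
                extra = extra[np.linalg.norm(extra, axis=1) < 0.6]
                pos = np.vstack([pos, extra])[: cfg.n_bg_dipoles]
            gain = _gain_matrix(self.model, np.vstack(
                [self.montage.positions, ideal_position(cfg.recorded_reference)]),
                pos)
            mom = rng.normal(size=(len(pos), 3))
            mom /= np.linalg.norm(mom, axis=1, keepdims=True)
            maps = np.stack([gain[:, 3 * i:3 * i + 3] @ mom[i]
                             for i in range(len(pos))], axis=1)     # (E, nbg)
            tc = rng.standard_normal((len(pos), T))
            sos = signal.butter(2, cfg.bg_cutoff_hz, fs=cfg.sfreq, output="sos")
            tc = signal.sosfiltfilt(sos, tc, axis=1)
            bg = maps @ tc
            rms = np.sqrt(np.mean(bg[:-1] ** 2))   # scalp channels only
            data += bg * (cfg.bg_rms_uv / rms)

        if cfg.sensor_rms_uv > 0:
            data += rng.normal(0.0, cfg.sensor_rms_uv, size=data.shape)

        # occasional large frontal deflections (artifact-rejection fodder)
        art_idx = [self._gen_labels.index(l) for l in FRONTAL_ARTIFACT_CHANNELS
                   if l in self._gen_labels]
        t_local = np.arange(int(round(0.8 * cfg.sfreq))) * dt
        for onset in onsets[rng.random(n_trials) < cfg.artifact_prob]:
            center = rng.uniform(0.0, 0.5)
            bump = (cfg.artifact_amp_uv * rng.choice([-1.0, 1.0])
                    * np.exp(-(((t_local - center) / 0.12) ** 2)))
            i0 = int(round(onset * cfg.sfreq))
            data[art_idx, i0:i0 + len(bump)] += bump[None, :]

        # reference subtraction: recorded against FCz (last generation row)
        data = data[:-1] - data[-1][None, :]
        rec = ScalpRecording(
            data=data, labels=self.montage.labels, sfreq=cfg.sfreq,
            reference=f"recorded:{cfg.recorded_reference}",
        )
        ev = pd.DataFrame({"onset_s": onsets, "condition": conds})
        return rec, ev


def generate_cohort(cfg: SynthConfig | None = None,
                    montage: ElectrodeMontage | None = None,
                    model: HeadModel | None = None) -> SynthCohort:
    """Build the (lazy) cohort for a config; see :class:`SynthCohort`."""
    return SynthCohort(cfg or SynthConfig(), montage=montage, model=model)


# ---------------------------------------------------------------------------
# fixture output


def write_fixture(cohort: SynthCohort, out_dir, subjects=None) -> list[Path]:
    """Write delimited recordings, event tables, montage and ground truth.

    Layout: ``montage.sfp``, ``ground_truth.json`` and, per subject/session,
    ``sub-XX_ses-Y_eeg.csv`` (samples x channels, header row of labels) with a
    JSON sidecar (sampling rate, reference) and ``sub-XX_ses-Y_events.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    write_sfp(cohort.montage, out / "montage.sfp")
    written.append(out / "montage.sfp")
    gt_all = {}
    subjects = range(cohort.cfg.n_subjects) if subjects is None else subjects
    for i in subjects:
        sub = cohort.subject(i)
        gt_all[f"sub-{i:02d}"] = sub.ground_truth
        for s, (rec, ev) in enumerate(zip(sub.sessions, sub.events)):
            stem = out / f"sub-{i:02d}_ses-{s + 1}"
            from .io import write_recording
            write_recording(rec, stem.with_suffix(".csv"))
            ev.to_csv(f"{stem}_events.csv", index=False)
            written += [stem.with_suffix(".csv"), Path(f"{stem}_events.csv")]
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"config_seed": cohort.cfg.seed, "subjects": gt_all}, fh,
                  indent=1)
    written.append(out / "ground_truth.json")
    return written
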