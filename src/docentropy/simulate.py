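"""Synthetic cohort generator.

No public DOC-EEG dataset accompanies the analysis this package implements,
so validation runs on synthetic cohorts built to carry the statistical
structure the analysis assumes:

* signal irregularity is a controlled monotone dial: each channel is a
  mixture ``(1 - irregularity) * oscillation + irregularity * filtered
  noise``, with the oscillation a random-phase 1-4 Hz + 8-12 Hz pair and the
  noise 0.3-100 Hz band-limited Gaussian — the simplest family in which ApEn
  increases monotonically with one parameter;
* UWS subjects are less irregular than MCS subjects; pain stimulation raises
  irregularity on the unaffected hemisphere (more in MCS) and leaves the
  affected hemisphere essentially flat;
* channels within a hemisphere share a latent source with group-dependent
  weight, so cross-approximate entropy falls as coupling rises;
* 12-month improvement follows a clamped linear-probability model in the
  CRS-R score and selected entropy responses.

Two output tiers share one latent parameterization: ``signals=True`` emits
full 16-channel recordings per condition (the entropy pipeline then measures
ApEn/C-ApEn from them); ``signals=False`` emits entropy tables directly
through a fixed affine proxy map from the latent parameters, which makes
large-n statistical validation (null calibration, coefficient recovery)
affordable. The proxy constants were calibrated once against the signal
model and are part of the generator definition.

Determinism: one master seed; per-subject streams come from
``SeedSequence(seed, spawn_key=(subject_index,))`` so cohorts are
order-independent and bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .channels import DEFAULT_PAIRS, RAW_LABELS, RELABELED, PairSpec, relabel_map
from .io import EEGRecording
from .prognosis import classify_improvement

logger = logging.getLogger(__name__)

GROUPS = ("UWS", "MCS")
DIAGNOSES = ("TBI", "stroke", "other")

#: Affine proxy map from latent irregularity/coupling to entropy scale,
#: calibrated once against the signal model on its steep segment
#: (irregularity 0.1-0.5; see docs/methods.md): ApEn ~ a0 + a1 *
#: irregularity; C-ApEn sits slightly above the ApEn level of its channels
#: and falls weakly with coupling.
APEN_PROXY = {"a0": 0.24, "a1": 2.0}
CAPEN_PROXY = {"b0": 0.27, "b1": 2.0, "b_coupling": -0.02}
#: Per-channel noise on entropy levels and on pain-rest differences
#: (entropy units), matching the spread the signal tier produces (levels
#: inherit the persistent per-channel irregularity trait; differences
#: cancel it and carry only measurement noise).
LEVEL_NOISE_SD = 0.16
DIFF_NOISE_SD = 0.05

#: Conditional 12-month category mixes given improvement status. Improved
#: UWS subjects land in MCS or severe disability; improved MCS subjects in
#: severe/moderate disability or good recovery; non-improved UWS subjects
#: rarely die, non-improved MCS subjects stay MCS.
UPGRADE_MIX = {
    "UWS": (("MCS", 12 / 25), ("severe_disability", 13 / 25)),
    "MCS": (("severe_disability", 35 / 42), ("moderate_disability", 5 / 42),
            ("good_recovery", 2 / 42)),
}
NO_UPGRADE_MIX = {
    "UWS": (("VS", 72 / 73), ("death", 1 / 73)),
    "MCS": (("MCS", 1.0),),
}


def _as_group_map(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {g: float(value[g]) for g in GROUPS}
    else:
        out = {g: float(value) for g in GROUPS}
    for v in out.values():
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    return out


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the modeled study: 98 UWS + 64 MCS subjects, 500 Hz,
    32,768-sample analysis epochs, lower irregularity (hence ApEn) in UWS,
    pain gains concentrated on the unaffected hemisphere and larger in MCS,
    stronger within-hemisphere coupling (hence lower C-ApEn) in UWS, and an
    improvement model calibrated to ~26% (UWS) / ~66% (MCS) upgrade rates.
    """

    n_uws: int = 98
    n_mcs: int = 64
    fs: float = 500.0
    epoch_len: int = 32768
    irregularity_uws: float = 0.20
    irregularity_mcs: float = 0.35
    irregularity_sd: float = 0.05
    channel_irregularity_sd: float = 0.08
    affected_deficit: float = 0.06
    pain_gain_unaffected: Mapping[str, float] | float = field(
        default_factory=lambda: {"UWS": 0.06, "MCS": 0.16})
    pain_gain_affected: Mapping[str, float] | float = field(
        default_factory=lambda: {"UWS": 0.0, "MCS": 0.0})
    coupling_uws: float = 0.5
    coupling_mcs: float = 0.3
    outcome_coefficients: dict[str, float] = field(
        default_factory=lambda: {"intercept": 0.01, "crs_r": 0.035,
                                 "P_A": 1.0, "C_U-MT_U": 0.6})
    diagnosis_mix: dict[str, float] = field(
        default_factory=lambda: {"TBI": 0.50, "stroke": 0.45, "other": 0.05})
    crs_r_mean: Mapping[str, float] | float = field(
        default_factory=lambda: {"UWS": 5.0, "MCS": 13.0})
    crs_r_sd: float = 2.5
    p_unknown_side: float = 0.15
    signal_scale_uv: float = 15.0
    two_epoch_pain: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_uws < 1 or self.n_mcs < 1:
            raise ValueError("need at least one subject per group")
        if self.epoch_len < 1000:
            raise ValueError("epoch_len must be >= 1000 samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for name in ("irregularity_uws", "irregularity_mcs", "coupling_uws",
                     "coupling_mcs", "p_unknown_side"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        self.pain_gain_unaffected = _as_group_map(
            self.pain_gain_unaffected, "pain_gain_unaffected")
        self.pain_gain_affected = _as_group_map(
            self.pain_gain_affected, "pain_gain_affected")
        self.crs_r_mean = _as_group_map(self.crs_r_mean, "crs_r_mean")
        if set(self.diagnosis_mix) != set(DIAGNOSES):
            raise ValueError(f"diagnosis_mix must cover {DIAGNOSES}")
        if abs(sum(self.diagnosis_mix.values()) - 1.0) > 1e-9:
            raise ValueError("diagnosis_mix must sum to 1")

    def irregularity(self, group: str) -> float:
        return self.irregularity_uws if group == "UWS" else self.irregularity_mcs

    def coupling(self, group: str) -> float:
        return self.coupling_uws if group == "UWS" else self.coupling_mcs


@dataclass
class SubjectRecord:
    """Baseline metadata plus the generated 12-month outcome."""

    subject_id: str
    age: float
    sex: str
    duration: float
    diagnosis: str
    group: str
    crs_r: int
    affected_side: str        # what imaging reports: left/right/unknown
    true_affected_side: str   # generator ground truth
    mgos_12m: str = ""
    improved: int = -1


def generate_channel_signal(irregularity: float, epoch_len: int, fs: float,
                            rng: np.random.Generator) -> np.ndarray:
    """One zero-mean unit-SD channel: oscillation/noise mixture.

    ``irregularity`` in [0, 1] weights 0.3-100 Hz band-limited Gaussian
    noise against a random-phase two-component (1-4 Hz and 8-12 Hz)
    oscillation; ApEn of the result increases monotonically with the
    parameter.
    """
    if not (np.isfinite(irregularity) and 0.0 <= irregularity <= 1.0):
        raise ValueError("irregularity must be a finite fraction in [0, 1]")
    if epoch_len < 8 or fs <= 0:
        raise ValueError("epoch_len and fs must be positive (epoch_len >= 8)")
    t = np.arange(epoch_len) / fs
    f_delta = rng.uniform(1.0, 4.0)
    f_alpha = rng.uniform(8.0, 12.0)
    osc = (np.sin(2 * np.pi * f_delta * t + rng.uniform(0, 2 * np.pi))
           + np.sin(2 * np.pi * f_alpha * t + rng.uniform(0, 2 * np.pi)))
    osc /= osc.std()
    high = min(100.0, 0.99 * fs / 2)
    b, a = sps.butter(4, [0.3 / (fs / 2), high / (fs / 2)], btype="band")
    pad = 200  # trimmed margin absorbs filtfilt edge transients
    noise = sps.filtfilt(b, a, rng.standard_normal(epoch_len + 2 * pad))
    noise = noise[pad:-pad]
    noise /= noise.std()
    x = (1.0 - irregularity) * osc + irregularity * noise
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _subject_rng(config: CohortConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(index,)))


def _latent_parameters(config: CohortConfig, group: str,
                       rng: np.random.Generator) -> dict:
    """Per-subject latent irregularities and pain gains per hemisphere role."""
    base = float(np.clip(rng.normal(config.irregularity(group),
                                    config.irregularity_sd), 0.02, 0.98))
    lat = {
        "base": base,
        "irr_affected": float(np.clip(base - config.affected_deficit, 0.02, 0.98)),
        "irr_unaffected": base,
        "gain_affected": config.pain_gain_affected[group],
        "gain_unaffected": config.pain_gain_unaffected[group],
        "coupling": config.coupling(group),
    }
    lat["irr_affected_pain"] = float(np.clip(
        lat["irr_affected"] + lat["gain_affected"], 0.02, 0.98))
    lat["irr_unaffected_pain"] = float(np.clip(
        lat["irr_unaffected"] + lat["gain_unaffected"], 0.02, 0.98))
    return lat


def _proxy_entropy_tables(subject_id: str, lat: dict, rng: np.random.Generator,
                          pairs: PairSpec) -> tuple[list, list]:
    """Per-subject ApEn / C-ApEn rows from the latent parameters.

    Eyes-closed levels follow the affine proxy map plus between-subject
    channel noise; the pain condition adds the hemisphere's irregularity
    gain (through the same map) plus difference noise, so pain-minus-rest
    contrasts center on ``a1 * gain``.
    """
    a0, a1 = APEN_PROXY["a0"], APEN_PROXY["a1"]
    b0, b1, bc = CAPEN_PROXY["b0"], CAPEN_PROXY["b1"], CAPEN_PROXY["b_coupling"]
    apen_rows = []
    capen_rows = []
    level = {}
    for chan in RELABELED:
        side = "affected" if chan.endswith("_A") else "unaffected"
        ec = a0 + a1 * lat[f"irr_{side}"] + rng.normal(0, LEVEL_NOISE_SD)
        pain = (ec + a1 * (lat[f"irr_{side}_pain"] - lat[f"irr_{side}"])
                + rng.normal(0, DIFF_NOISE_SD))
        level[chan] = (ec, pain)
        apen_rows.append((subject_id, "eyes_closed", chan, max(ec, 0.0)))
        apen_rows.append((subject_id, "pain", chan, max(pain, 0.0)))
    for tmpl, targ in pairs.all_pairs:
        side = "affected" if tmpl.endswith("_A") else "unaffected"
        ec = (b0 + b1 * lat[f"irr_{side}"] + bc * lat["coupling"]
              + rng.normal(0, LEVEL_NOISE_SD))
        pain = (ec + b1 * (lat[f"irr_{side}_pain"] - lat[f"irr_{side}"])
                + rng.normal(0, DIFF_NOISE_SD))
        name = f"{tmpl}-{targ}"
        capen_rows.append((subject_id, "eyes_closed", name, max(ec, 0.0), 0, False))
        capen_rows.append((subject_id, "pain", name, max(pain, 0.0), 0, False))
    return apen_rows, capen_rows


def generate_outcome(record: SubjectRecord, entropy_features: Mapping[str, float],
                     coefficients: Mapping[str, float],
                     rng: np.random.Generator) -> tuple[str, int]:
    """Draw the 12-month mGOS category from the linear-probability model.

    ``entropy_features`` maps predictor names (channels/pairs, pain-minus-
    rest differences) to values; ``crs_r`` is taken from the record. The
    linear predictor is clamped to [0, 1] (logged when clamping occurs);
    improvement then upgrades the category according to the group's
    conditional outcome mix.
    """
    p = 0.0
    for name, w in coefficients.items():
        if name == "intercept":
            p += w
        elif name == "crs_r":
            p += w * record.crs_r
        else:
            if name not in entropy_features:
                raise KeyError(f"outcome coefficient {name!r} has no matching "
                               "entropy feature")
            p += w * entropy_features[name]
    if p < 0.0 or p > 1.0:
        logger.debug("improvement probability %.3f clamped for %s",
                     p, record.subject_id)
        p = float(np.clip(p, 0.0, 1.0))
    improved = int(rng.random() < p)
    mix = UPGRADE_MIX[record.group] if improved else NO_UPGRADE_MIX[record.group]
    cats = [c for c, _ in mix]
    probs = np.array([w for _, w in mix])
    mgos = str(rng.choice(cats, p=probs / probs.sum()))
    assert classify_improvement(record.group, mgos) == improved
    return mgos, improved


def _make_record(config: CohortConfig, group: str, index: int,
                 rng: np.random.Generator) -> SubjectRecord:
    age = float(np.clip(rng.normal(46.0, 14.0), 17.0, 73.0))
    sex = "male" if rng.random() < 0.72 else "female"
    duration = float(rng.integers(61, 181))
    diagnosis = str(rng.choice(DIAGNOSES,
                               p=[config.diagnosis_mix[d] for d in DIAGNOSES]))
    crs = int(np.clip(np.round(rng.normal(config.crs_r_mean[group],
                                          config.crs_r_sd)), 0, 23))
    true_side = "left" if rng.random() < 0.5 else "right"
    reported = "unknown" if rng.random() < config.p_unknown_side else true_side
    return SubjectRecord(
        subject_id=f"S{index:04d}", age=round(age, 1), sex=sex,
        duration=duration, diagnosis=diagnosis, group=group, crs_r=crs,
        affected_side=reported, true_affected_side=true_side)


def _signal_recordings(config: CohortConfig, record: SubjectRecord, lat: dict,
                       rng: np.random.Generator) -> list[EEGRecording]:
    """Eyes-closed and pain recordings in raw 10-20 labels, microvolts.

    Each channel carries a persistent irregularity offset (its topographic
    trait, drawn once per subject and shared by both conditions, so
    pain-minus-rest differences cancel it). The hemispheric latent source
    suppresses this between-channel heterogeneity as the coupling weight
    rises, which is what makes pair C-ApEn fall with coupling.
    """
    c = lat["coupling"]
    w_own, w_shared = np.sqrt(1.0 - c), np.sqrt(c)
    side_of_label = relabel_map(record.true_affected_side)  # 10-20 -> _A/_U
    chan_offset = {lab: rng.normal(0.0, config.channel_irregularity_sd)
                   for lab in RAW_LABELS}
    conditions = ["eyes_closed", "pain"]
    if config.two_epoch_pain:
        conditions.append("pain_second_epoch")
    out = []
    for cond in conditions:
        suffix = "" if cond == "eyes_closed" else "_pain"
        latent = {
            "A": generate_channel_signal(lat[f"irr_affected{suffix}"],
                                         config.epoch_len, config.fs, rng),
            "U": generate_channel_signal(lat[f"irr_unaffected{suffix}"],
                                         config.epoch_len, config.fs, rng),
        }
        data = np.empty((16, config.epoch_len))
        for i, lab in enumerate(RAW_LABELS):
            role = side_of_label[lab][-1]  # 'A' or 'U'
            irr_hemi = lat[f"irr_{'affected' if role == 'A' else 'unaffected'}{suffix}"]
            irr_ch = float(np.clip(irr_hemi + chan_offset[lab], 0.02, 0.98))
            own = generate_channel_signal(irr_ch, config.epoch_len,
                                          config.fs, rng)
            data[i] = (w_own * own + w_shared * latent[role]) * config.signal_scale_uv
        out.append(EEGRecording(subject_id=record.subject_id, condition=cond,
                                fs=config.fs, channel_labels=list(RAW_LABELS),
                                data=data))
    return out


def generate_subject(config: CohortConfig, group: str, index: int,
                     signals: bool = True):
    """One subject: metadata, proxy entropy rows, optional recordings.

    Returns (SubjectRecord, apen_rows, capen_rows, recordings). The
    recordings list is empty when ``signals=False``. Reproducible from
    (config, index) alone.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    rng = _subject_rng(config, index)
    record = _make_record(config, group, index, rng)
    lat = _latent_parameters(config, group, rng)
    apen_rows, capen_rows = _proxy_entropy_tables(
        record.subject_id, lat, rng, DEFAULT_PAIRS)

    features = _difference_features(record.subject_id, apen_rows, capen_rows)
    record.mgos_12m, record.improved = generate_outcome(
        record, features, config.outcome_coefficients, rng)

    recordings = _signal_recordings(config, record, lat, rng) if signals else []
    return record, apen_rows, capen_rows, recordings


def _difference_features(subject_id: str, apen_rows: list,
                         capen_rows: list) -> dict[str, float]:
    ec = {r[2]: r[3] for r in apen_rows if r[1] == "eyes_closed"}
    pain = {r[2]: r[3] for r in apen_rows if r[1] == "pain"}
    feats = {chan: pain[chan] - ec[chan] for chan in ec}
    ec_p = {r[2]: r[3] for r in capen_rows if r[1] == "eyes_closed"}
    pain_p = {r[2]: r[3] for r in capen_rows if r[1] == "pain"}
    feats.update({p: pain_p[p] - ec_p[p] for p in ec_p})
    return feats


@dataclass
class SyntheticCohort:
    """Generator output: metadata, proxy entropy tables, recordings."""

    config: CohortConfig
    meta: pd.DataFrame
    apen_proxy: pd.DataFrame
    capen_proxy: pd.DataFrame
    recordings: list[EEGRecording]


def generate_cohort(config: CohortConfig, signals: bool = True) -> SyntheticCohort:
    """Full cohort; a pure function of the config (bit-identical reruns).

    Subject i's random stream depends only on (seed, i), so per-subject
    output is independent of cohort ordering and of the other subjects.
    """
    records = []
    apen_rows: list = []
    capen_rows: list = []
    recordings: list[EEGRecording] = []
    groups = ["UWS"] * config.n_uws + ["MCS"] * config.n_mcs
    for i, group in enumerate(groups):
        rec, arows, crows, recs = generate_subject(config, group, i, signals)
        records.append(rec)
        apen_rows.extend(arows)
        capen_rows.extend(crows)
        recordings.extend(recs)
    meta = pd.DataFrame([asdict(r) for r in records])
    apen_proxy = pd.DataFrame(
        apen_rows, columns=["subject_id", "condition", "channel", "apen"])
    capen_proxy = pd.DataFrame(
        capen_rows, columns=["subject_id", "condition", "pair", "capen",
                             "n_zero_match", "unreliable"])
    return SyntheticCohort(config=config, meta=meta, apen_proxy=apen_proxy,
                           capen_proxy=capen_proxy, recordings=recordings)


def inject_spike(rec: EEGRecording, sample: int, amplitude: float = 500.0,
                 channel: int = 0) -> EEGRecording:
    """Copy of the recording with an amplitude artifact at one sample."""
    data = rec.data.copy()
    data[channel, sample] += amplitude
    out = EEGRecording(subject_id=rec.subject_id, condition=rec.condition,
                       fs=rec.fs, channel_labels=list(rec.channel_labels),
                       data=data)
    return out
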