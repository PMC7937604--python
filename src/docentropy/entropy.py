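"""Approximate entropy (ApEn) and cross-approximate entropy (C-ApEn).

ApEn(m, r) of a series u of length N is Phi^m(r) - Phi^{m+1}(r), where
Phi^m is the average over the N-m+1 templates x_i = (u_i, ..., u_{i+m-1})
of ln C_i^m(r), and C_i^m(r) is the fraction of templates within Chebyshev
distance r of x_i (self-match included, the classical convention). Higher
values mean a less predictable, more complex signal.

C-ApEn is the two-series analogue: templates from one series are matched
against targets from the other, measuring asynchrony between two channels
(lower = more synchronized). Both series are z-scored before matching and r
is taken relative to unit SD, because cross-channel amplitudes differ.
Because self-matches are included in ApEn, capen(u, u) equals
apen(standardize(u)) exactly.

Defaults m=2, r=0.2*SD are the canonical ApEn settings for EEG epochs of
this length (32,768 samples at 500 Hz = 65.536 s).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from ._kernels import phi_terms
from .channels import DEFAULT_PAIRS, PairSpec

if TYPE_CHECKING:  # pragma: no cover
    from .io import EEGRecording

logger = logging.getLogger(__name__)

CONDITIONS = ("eyes_closed", "pain")

#: Fraction of zero-match templates above which a C-ApEn value is flagged.
ZERO_MATCH_LIMIT = 0.10


@dataclass(frozen=True)
class ApEnParams:
    """Embedding dimension m, tolerance r as a fraction of SD, epoch length."""

    m: int = 2
    r_factor: float = 0.2
    n_points: int = 32768

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not np.isfinite(self.r_factor) or self.r_factor <= 0:
            raise ValueError("r_factor must be a positive finite fraction of SD")
        if self.n_points <= self.m + 1:
            raise ValueError("n_points must exceed m + 1")


@dataclass(frozen=True)
class CApEnResult:
    """C-ApEn value with zero-match diagnostics.

    ln C is undefined for a template with no match; such templates are
    excluded from the average and counted here. ``unreliable`` is set when
    more than 10% of templates at either embedding level had no match.
    """

    value: float
    n_zero_match_m: int
    n_zero_match_m1: int
    unreliable: bool

    def __float__(self) -> float:
        return float(self.value)


def standardize(u: np.ndarray) -> np.ndarray:
    """Z-score (population SD); constant series are only mean-centered."""
    u = np.asarray(u, dtype=float)
    sd = u.std()
    return (u - u.mean()) / sd if sd > 0 else u - u.mean()


def _validate_series(u: np.ndarray, p: ApEnParams, name: str = "series") -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(u)):
        raise ValueError(f"{name} contains non-finite samples")
    if len(u) <= p.m + 1:
        raise ValueError(f"{name} too short ({len(u)} samples) for m={p.m}")
    if len(u) != p.n_points:
        raise ValueError(
            f"{name} has {len(u)} samples but params.n_points={p.n_points}")
    return u


def _params_for(u: np.ndarray, p: ApEnParams | None) -> ApEnParams:
    return p if p is not None else ApEnParams(n_points=len(np.asarray(u)))


def apen(u: np.ndarray, p: ApEnParams | None = None) -> float:
    """Approximate entropy of one channel epoch.

    The tolerance is r_factor * SD(u); a constant series (SD = 0) returns 0
    with a warning, as all templates are identical and the series carries no
    complexity.
    """
    p = _params_for(u, p)
    u = _validate_series(u, p)
    if u.std() == 0:
        warnings.warn("constant series: ApEn defined as 0", stacklevel=2)
        return 0.0
    phi_m, phi_m1, _, _ = phi_terms(standardize(u), None, p.m, p.r_factor)
    return phi_m - phi_m1


def capen(u: np.ndarray, v: np.ndarray, p: ApEnParams | None = None,
          return_info: bool = False) -> float | CApEnResult:
    """Cross-approximate entropy; templates from ``u``, targets from ``v``.

    Both series are z-scored internally and r = r_factor on the unit-SD
    scale. Templates with zero matches are excluded from the average; if
    more than 10% of templates at either level had no match the value is
    flagged unreliable (and returned).
    """
    p = _params_for(u, p)
    u = _validate_series(u, p, "template series")
    v = _validate_series(np.asarray(v, dtype=float), p, "target series")
    phi_m, phi_m1, nz_m, nz_m1 = phi_terms(
        standardize(u), standardize(v), p.m, p.r_factor)
    n_m = p.n_points - p.m + 1
    n_m1 = p.n_points - p.m
    unreliable = (nz_m / n_m > ZERO_MATCH_LIMIT) or (nz_m1 / n_m1 > ZERO_MATCH_LIMIT)
    res = CApEnResult(phi_m - phi_m1, nz_m, nz_m1, unreliable)
    if unreliable:
        warnings.warn(
            f"C-ApEn unreliable: {nz_m}/{n_m} (m) and {nz_m1}/{n_m1} (m+1) "
            "templates had zero matches", stacklevel=2)
    return res if return_info else res.value


def _grouped_recordings(
        recordings: Iterable["EEGRecording"],
) -> dict[str, dict[str, "EEGRecording"]]:
    """Group recordings by subject, keeping only subjects with both
    conditions; incomplete subjects are skipped and logged."""
    by_subject: dict[str, dict[str, "EEGRecording"]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, {})[rec.condition] = rec
    complete = {}
    for sid, conds in sorted(by_subject.items()):
        missing = [c for c in CONDITIONS if c not in conds]
        if missing:
            logger.warning("subject %s skipped: missing condition(s) %s",
                           sid, missing)
            continue
        complete[sid] = conds
    return complete


def apen_matrix(recordings: Iterable["EEGRecording"],
                p: ApEnParams | None = None) -> pd.DataFrame:
    """ApEn for every subject x condition x channel, as a tidy table.

    Recordings must already be epoch-selected and remapped to the
    affected/unaffected montage. Columns: subject_id, condition, channel,
    apen.
    """
    rows = []
    for sid, conds in _grouped_recordings(recordings).items():
        for cond in CONDITIONS:
            rec = conds[cond]
            pp = p if p is not None else ApEnParams(n_points=rec.data.shape[1])
            for label, series in zip(rec.channel_labels, rec.data):
                rows.append((sid, cond, label, apen(series, pp)))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "channel", "apen"])


def capen_pairs(recordings: Iterable["EEGRecording"],
                pairs: PairSpec = DEFAULT_PAIRS,
                p: ApEnParams | None = None) -> pd.DataFrame:
    """C-ApEn for every subject x condition x designated pair.

    The central electrode (first element of each pair) supplies the
    templates. Columns: subject_id, condition, pair, capen, n_zero_match,
    unreliable.
    """
    rows = []
    for sid, conds in _grouped_recordings(recordings).items():
        for cond in CONDITIONS:
            rec = conds[cond]
            pp = p if p is not None else ApEnParams(n_points=rec.data.shape[1])
            idx = {lab: i for i, lab in enumerate(rec.channel_labels)}
            for tmpl, targ in pairs.all_pairs:
                res = capen(rec.data[idx[tmpl]], rec.data[idx[targ]], pp,
                            return_info=True)
                rows.append((sid, cond, f"{tmpl}-{targ}", res.value,
                             res.n_zero_match_m + res.n_zero_match_m1,
                             res.unreliable))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "pair",
                                       "capen", "n_zero_match", "unreliable"])


def pair_group_means(pair_table: pd.DataFrame,
                     pairs: PairSpec = DEFAULT_PAIRS) -> pd.DataFrame:
    """Local/distant x affected/unaffected mean C-ApEn per subject x condition."""
    rows = []
    for (sid, cond), sub in pair_table.groupby(["subject_id", "condition"]):
        vals = sub.set_index("pair")["capen"]
        for group, names in pairs.groups().items():
            rows.append((sid, cond, group, float(vals.loc[names].mean())))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "group", "capen"])
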