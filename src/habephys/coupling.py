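"""Paired-recording synchrony analysis and dye-coupling quantification.

Synchrony is the Spearman correlation of the filtered pre- and
post-junctional traces over an analysis window (step onset to 3 s after
offset by default).  Dye positivity uses strict-inequality intensity
criteria against per-ROI surround statistics, and the coupling summary
reproduces the incidence / marker-fraction bookkeeping from per-recording
coupled-cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .model import PairedTraces, StepProtocol, VoltageTrace
from .features import lowpass_10Hz, _baseline
from .stats import mann_whitney_u

RHO_MIN_DEFAULT = 0.5


def synchrony(pair: PairedTraces, protocol: Optional[StepProtocol] = None,
              rho_min: float = RHO_MIN_DEFAULT,
              post_offset_s: float = 3.0,
              min_excursion_mV: float = 0.5):
    """Spearman rho between the filtered pair over the analysis window.

    Returns ``(rho, coupled)`` with ``coupled = rho > rho_min``.  Without
    a protocol the full trace is used.  When either filtered trace moves
    less than ``min_excursion_mV`` peak-to-peak over the window, there is
    no signal to correlate (rank correlation would amplify numerical
    drift); rho is reported as 0 and the pair as uncoupled.
    """
    fpre = lowpass_10Hz(pair.pre).v_mV
    fpost = lowpass_10Hz(pair.post).v_mV
    if protocol is not None:
        fs = pair.pre.fs
        i0 = int(round(protocol.t_on * fs))
        i1 = min(fpre.size,
                 int(round((protocol.t_off + post_offset_s) * fs)))
        fpre, fpost = fpre[i0:i1], fpost[i0:i1]
    if np.ptp(fpre) < min_excursion_mV or np.ptp(fpost) < min_excursion_mV:
        return 0.0, False
    # decimate to ~1 kHz: the filtered signals carry no content above
    # 10 Hz and full-rate rank correlation is needlessly slow
    step = max(1, int(round(pair.pre.fs / 1000.0)))
    rho = float(sstats.spearmanr(fpre[::step], fpost[::step]).statistic)
    return rho, rho > rho_min


def amplitude_ratio(trace: VoltageTrace, protocol: StepProtocol,
                    post_window_s: float = 3.0,
                    min_rebound_mV: float = 0.5) -> float:
    """Rebound amplitude relative to the preceding hyperpolarization.

    ratio = (peak filtered post-offset depolarization above baseline) /
    (peak filtered hyperpolarizing deflection during the step); 0 when
    no rebound rises above baseline.  ``min_rebound_mV`` is a dead band
    absorbing the zero-phase filter's small overshoot at the step edge.
    """
    if protocol.amp_pA >= 0:
        raise ValueError("amplitude ratio requires a hyperpolarizing step")
    f = lowpass_10Hz(trace).v_mV
    fs = trace.fs
    base = _baseline(f, fs, protocol.t_on)
    i_on = int(round(protocol.t_on * fs))
    i_off = int(round(protocol.t_off * fs))
    i_end = min(f.size, int(round((protocol.t_off + post_window_s) * fs)))
    hyper = base - f[i_on:i_off].min()
    if hyper <= 0:
        raise ValueError("no hyperpolarizing deflection during the step")
    rebound = f[i_off:i_end].max() - base
    if rebound < min_rebound_mV:
        return 0.0
    return float(rebound / hyper)


@dataclass
class DyeCall:
    nb_positive: bool
    alexa_negative: bool
    coupled: bool
    excluded: bool


_ROI_COLUMNS = ("nb_mean", "alexa_mean", "nb_surround_mean",
                "nb_surround_sd", "alexa_surround_mean",
                "alexa_surround_sd")


def dye_positive(roi) -> DyeCall:
    """Apply the intensity criteria to one ROI record (mapping-like).

    NB positive iff NB mean > surround mean + 2 SD (strict); Alexa
    negative iff Alexa mean < surround mean + 0.5 SD (strict).  Coupled
    iff NB+ and Alexa- and not the recorded cell; excluded (double
    positive) iff NB+ and not Alexa-.
    """
    for c in _ROI_COLUMNS:
        if c not in roi or roi[c] is None:
            raise KeyError(f"ROI record missing channel field {c!r}")
    nb_pos = roi["nb_mean"] > roi["nb_surround_mean"] + 2.0 * roi["nb_surround_sd"]
    al_neg = roi["alexa_mean"] < (roi["alexa_surround_mean"]
                                  + 0.5 * roi["alexa_surround_sd"])
    recorded = bool(roi.get("is_recorded_cell", False))
    coupled = bool(nb_pos and al_neg and not recorded)
    excluded = bool(nb_pos and not al_neg)
    return DyeCall(nb_positive=bool(nb_pos), alexa_negative=bool(al_neg),
                   coupled=coupled, excluded=excluded)


def apply_dye_criteria(rois: pd.DataFrame) -> pd.DataFrame:
    """Vectorized dye_positive over an ROI table; appends call columns."""
    out = rois.copy()
    calls = [dye_positive(row) for _, row in rois.iterrows()]
    out["nb_positive"] = [c.nb_positive for c in calls]
    out["alexa_negative"] = [c.alexa_negative for c in calls]
    out["coupled"] = [c.coupled for c in calls]
    out["excluded"] = [c.excluded for c in calls]
    return out


def coupling_summary(recordings: Sequence[pd.DataFrame],
                     marker_columns: Sequence[str] = (),
                     condition_labels: Optional[Sequence[str]] = None):
    """Summarize dye coupling across recordings.

    ``recordings`` is one ROI table per recording (raw; criteria are
    applied here).  Returns a dict with per-recording coupled counts,
    incidence (fraction of recordings with >= 1 coupled cell), marker
    fractions among coupled cells and, when two condition labels are
    supplied, a Mann-Whitney comparison of per-recording counts.
    """
    if len(recordings) == 0:
        raise ValueError("no recordings supplied")
    per_rec = []
    marker_hits = {m: 0 for m in marker_columns}
    marker_totals = {m: 0 for m in marker_columns}
    for rec in recordings:
        table = apply_dye_criteria(rec)
        coupled = table[table["coupled"]]
        per_rec.append(int(len(coupled)))
        for m in marker_columns:
            if m in table.columns:
                known = coupled[coupled[m].notna()]
                marker_totals[m] += int(len(known))
                marker_hits[m] += int(known[m].astype(bool).sum())
    n_rec = len(per_rec)
    n_pos = int(sum(1 for c in per_rec if c > 0))
    summary = {
        "per_recording_coupled": per_rec,
        "n_recordings": n_rec,
        "n_recordings_with_coupling": n_pos,
        "incidence": n_pos / n_rec,
        "marker_fractions": {
            m: {"positive": marker_hits[m], "total": marker_totals[m],
                "fraction": (marker_hits[m] / marker_totals[m]
                             if marker_totals[m] else float("nan"))}
            for m in marker_columns
        },
    }
    if condition_labels is not None:
        labels = list(condition_labels)
        if len(labels) != n_rec:
            raise ValueError("one condition label per recording required")
        conds = sorted(set(labels))
        if len(conds) == 2:
            a = [c for c, l in zip(per_rec, labels) if l == conds[0]]
            b = [c for c, l in zip(per_rec, labels) if l == conds[1]]
            u, p = mann_whitney_u(a, b)
            summary["condition_comparison"] = {
                "conditions": conds, "U": u, "p": p,
            }
    return summary


def incidence_from_counts(positive: int, total: int) -> float:
    """Fraction helper for printed tallies (e.g. 19 of 22 -> 0.8636...)."""
    if total <= 0 or positive < 0 or positive > total:
        raise ValueError("need 0 <= positive <= total, total > 0")
    return positive / total
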