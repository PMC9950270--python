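"""Per-trial indicator extraction: the full named indicator vector.

Assembles the conditioned signals, stroke segmentation, EMD tremor
component and the indicator computations of the four indicator modules into
one named vector per trial, organized in seven domains (kinematics, force,
smoothness, tilt, frequency, amplitude, regularity).

Signal conventions
------------------
* Time-domain indicators are computed on the on-paper samples only
  (pen-in-air segments removed and the remainder concatenated): force is
  undefined mid-air.
* Frequency/amplitude spectra are computed on the on-paper concatenated,
  mean-removed *unfiltered* norms so the sub-2 Hz drawing oscillation keeps
  its share of total power.
* The "_T" (tremor) indicators are computed on the tremor component
  extracted from the full-length acceleration norm: tremor is a property of
  the limb, not of tip contact, and concatenation seams would corrupt the
  cycle-duration statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emd import extract_tremor
from .preprocess import preprocess, qc_exclude, segment_strokes
from .recording import PenRecording
from .indicators import regularity as reg
from .indicators import spectral as spc
from .indicators import time_domain as td

DOMAINS: dict[str, list[str]] = {
    "kinematics": ["Execution_Time", "Strokes_Num", "ConsPeakDiff_G_Avg", "ConsPeakDiff_G_CV"],
    "force": ["F_Avg", "F_CV", "F_OVS", "ConsPeakDiff_F_Avg", "ConsPeakDiff_F_CV", "NC_F"],
    "smoothness": ["NC_A", "NC_G", "SPARC_G_10", "SPARC_G_20", "SPARC_G_30",
                   "SPARC_G_40", "SPARC_G_45", "SPARC_G_50", "LDLJ_A", "LDLJ_G"],
    "tilt": ["Tilt_Avg", "Tilt_Var", "Tilt_CV"],
    "frequency": ["RPW_A_0-2", "RPW_A_2-4", "RPW_A_4-7", "RPW_A_8-12",
                  "RPW_G_0-2", "RPW_G_2-4", "RPW_G_4-7", "RPW_G_8-12",
                  "RPW_G_filt_max", "MHP_T"],
    "amplitude": ["RMS_A", "RMS_G", "RMS_G_filt_max", "SNR_T",
                  "Out_Lev_Rel_A", "Out_Lev_Rel_G", "AmpXOut_Lev_A", "AmpXOut_Lev_G"],
    "regularity": ["ApEn_T", "RR_T", "DET_T", "TSI_T", "G_Rate_max"],
}

ALL_INDICATORS: list[str] = [name for names in DOMAINS.values() for name in names]

_RPW_BAND_BY_SUFFIX = {"0-2": (0.0, 2.0), "2-4": (2.0, 4.0),
                       "4-7": (4.0, 7.0), "8-12": (8.0, 12.0)}


def extract_indicators(rec: PenRecording, subset: list[str] | None = None) -> dict:
    """Compute the indicator vector for one trial.

    Parameters
    ----------
    rec : PenRecording
    subset : list of indicator names, optional
        Restrict computation to these indicators (the rest are omitted);
        the expensive stages (EMD, recurrence) are skipped when no
        requested indicator needs them.

    Returns
    -------
    dict mapping indicator name -> float (NaN = missing), plus the keys
    ``qc_excluded`` (bool, >20-pen-lift rule) and ``tremor_peak_freq``.
    """
    want = set(subset) if subset is not None else set(ALL_INDICATORS)
    unknown = want - set(ALL_INDICATORS)
    if unknown:
        raise KeyError(f"unknown indicator(s): {sorted(unknown)}")

    sig = preprocess(rec)
    seg = segment_strokes(rec)
    out: dict = {name: float("nan") for name in ALL_INDICATORS if name in want}
    out["qc_excluded"] = qc_exclude(seg)
    out["tremor_peak_freq"] = float("nan")

    if not seg.any_contact:
        return out

    mask = seg.on_paper_mask
    force_on = sig.force[mask]
    acc_bp_on = sig.acc_mag_bp[mask]
    gyro_bp_on = sig.gyro_mag_bp[mask]
    tilt_on = sig.tilt[mask]
    acc_raw_on = sig.acc_mag_raw[mask] - sig.acc_mag_raw[mask].mean()
    gyro_raw_on = sig.gyro_mag_raw[mask] - sig.gyro_mag_raw[mask].mean()

    def wants(*names: str) -> bool:
        return any(n in want for n in names)

    # --- kinematics ---------------------------------------------------
    if wants("Execution_Time"):
        out["Execution_Time"] = td.execution_time(seg, rec.fs)
    if wants("Strokes_Num"):
        out["Strokes_Num"] = float(seg.n_strokes)
    if wants("ConsPeakDiff_G_Avg", "ConsPeakDiff_G_CV"):
        avg, cv = td.cons_peak_diff(gyro_bp_on)
        if "ConsPeakDiff_G_Avg" in want:
            out["ConsPeakDiff_G_Avg"] = avg
        if "ConsPeakDiff_G_CV" in want:
            out["ConsPeakDiff_G_CV"] = cv

    # --- force --------------------------------------------------------
    if wants("F_Avg", "F_CV", "F_OVS") and force_on.size >= 10:
        favg, fcv, fovs = td.force_stats(force_on)
        for name, val in (("F_Avg", favg), ("F_CV", fcv), ("F_OVS", fovs)):
            if name in want:
                out[name] = val
    if wants("ConsPeakDiff_F_Avg", "ConsPeakDiff_F_CV"):
        avg, cv = td.cons_peak_diff(force_on)
        if "ConsPeakDiff_F_Avg" in want:
            out["ConsPeakDiff_F_Avg"] = avg
        if "ConsPeakDiff_F_CV" in want:
            out["ConsPeakDiff_F_CV"] = cv
    if wants("NC_F"):
        out["NC_F"] = td.rate_of_changes(force_on, rec.fs)

    # --- smoothness ---------------------------------------------------
    if wants("NC_A"):
        out["NC_A"] = td.rate_of_changes(acc_bp_on, rec.fs)
    if wants("NC_G"):
        out["NC_G"] = td.rate_of_changes(gyro_bp_on, rec.fs)
    for pct in td.SPARC_THRESHOLDS:
        name = f"SPARC_G_{pct}"
        if name in want and gyro_bp_on.size >= 2 * rec.fs:
            out[name] = td.sparc(gyro_bp_on, rec.fs, pct)
    if wants("LDLJ_A") and acc_bp_on.size >= rec.fs:
        out["LDLJ_A"] = td.ldlj(acc_bp_on, rec.fs)
    if wants("LDLJ_G") and gyro_bp_on.size >= rec.fs:
        out["LDLJ_G"] = td.ldlj(gyro_bp_on, rec.fs)

    # --- tilt ---------------------------------------------------------
    if wants("Tilt_Avg", "Tilt_Var", "Tilt_CV") and tilt_on.size >= 10:
        tavg, tvar, tcv = td.tilt_stats(tilt_on)
        for name, val in (("Tilt_Avg", tavg), ("Tilt_Var", tvar), ("Tilt_CV", tcv)):
            if name in want:
                out[name] = val

    # --- frequency / amplitude (Welch spectra of raw norms) -----------
    need_spec_a = wants("RPW_A_0-2", "RPW_A_2-4", "RPW_A_4-7", "RPW_A_8-12",
                        "Out_Lev_Rel_A", "AmpXOut_Lev_A")
    need_spec_g = wants("RPW_G_0-2", "RPW_G_2-4", "RPW_G_4-7", "RPW_G_8-12",
                        "RPW_G_filt_max", "Out_Lev_Rel_G", "AmpXOut_Lev_G",
                        "RMS_G_filt_max")
    spec_a = spec_g = None
    if need_spec_a and acc_raw_on.size >= 250:
        spec_a = spc.welch_psd(acc_raw_on, rec.fs)
    if need_spec_g and gyro_raw_on.size >= 250:
        spec_g = spc.welch_psd(gyro_raw_on, rec.fs)

    for prefix, spec in (("A", spec_a), ("G", spec_g)):
        if spec is None:
            continue
        for suffix, band in _RPW_BAND_BY_SUFFIX.items():
            name = f"RPW_{prefix}_{suffix}"
            if name in want:
                out[name] = spc.relative_band_power(spec, band)
        if wants(f"Out_Lev_Rel_{prefix}", f"AmpXOut_Lev_{prefix}"):
            lev, amp = spc.outlier_level(spec)
            if f"Out_Lev_Rel_{prefix}" in want:
                out[f"Out_Lev_Rel_{prefix}"] = lev
            if f"AmpXOut_Lev_{prefix}" in want:
                out[f"AmpXOut_Lev_{prefix}"] = amp
    if spec_g is not None and "RPW_G_filt_max" in want:
        out["RPW_G_filt_max"] = spc.rpw_peak_band(spec_g)
    if spec_g is not None and "RMS_G_filt_max" in want:
        out["RMS_G_filt_max"] = spc.rms_filt_max(
            gyro_raw_on, rec.fs, spc.spectral_peak(spec_g))

    if wants("RMS_A") and acc_bp_on.size > 0:
        out["RMS_A"] = spc.windowed_rms(acc_bp_on, rec.fs, 10.0, reduce="mean")
    if wants("RMS_G") and gyro_bp_on.size > 0:
        out["RMS_G"] = spc.windowed_rms(gyro_bp_on, rec.fs, 10.0, reduce="mean")

    # --- tremor-dependent ("_T") and regularity -----------------------
    need_tremor = wants("MHP_T", "SNR_T", "ApEn_T", "RR_T", "DET_T", "TSI_T")
    if need_tremor and sig.acc_mag_raw.size >= 4 * rec.fs:
        trem = extract_tremor(sig.acc_mag_raw, rec.fs)
        out["tremor_peak_freq"] = trem.peak_freq
        if "MHP_T" in want:
            out["MHP_T"] = spc.mean_harmonic_power(trem)
        if "SNR_T" in want:
            out["SNR_T"] = spc.snr_tremor(trem)
        if trem.defined:
            if "ApEn_T" in want and trem.tremor.size >= 100:
                out["ApEn_T"] = reg.approximate_entropy(trem.tremor)
            if wants("RR_T", "DET_T") and trem.tremor.size >= 200:
                rr, det = reg.recurrence_measures(trem.tremor)
                if "RR_T" in want:
                    out["RR_T"] = rr
                if "DET_T" in want:
                    out["DET_T"] = det
            if "TSI_T" in want:
                out["TSI_T"] = reg.tremor_stability_index(trem.tremor, rec.fs)
    if wants("G_Rate_max") and gyro_bp_on.size >= rec.fs:
        out["G_Rate_max"] = reg.gyro_change_rate(gyro_bp_on, rec.fs)

    return out


def extract_table(recordings: list[PenRecording],
                  subset: list[str] | None = None,
                  drop_excluded: bool = True) -> pd.DataFrame:
    """Extract indicators for many trials into a tidy per-trial table.

    Trials failing the >20-pen-lift QC rule are dropped when
    ``drop_excluded`` (the ``qc_excluded`` column is kept either way).
    """
    rows = []
    for rec in recordings:
        row = {"subject_id": rec.subject_id, "group": rec.group,
               "hand": rec.hand, "trial": rec.trial}
        row.update(extract_indicators(rec, subset=subset))
        rows.append(row)
    df = pd.DataFrame(rows)
    if drop_excluded and len(df):
        df = df[~df["qc_excluded"]].reset_index(drop=True)
    return df
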