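"""File formats and pipeline configuration.

Canonical FID format is plain columnar text: ``# key: value`` header
lines (n_points, spectral_width_hz, spectrometer_freq_mhz, nucleus,
ref_ppm, provenance, plus free extra keys for parameter provenance),
then ``index,time_s,real,imag`` rows.  Floats are written with 17
significant digits so write/read round-trips bit-exactly.

A minimal NIfTI-MRS export/import (single voxel: complex time-domain
data, dwell time, spectrometer frequency, nucleus) is provided for
interoperability; it requires ``nibabel``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .denoise import DenoiseParams, default_rank
from .evaluate import ExperimentConfig
from .signals import AcquisitionParams, FIDSignal, Nucleus, PeakTable, ResonanceLine
from .simulate import default_acquisition, default_peak_table, stroke_peak_table

__all__ = [
    "write_fid",
    "read_fid",
    "write_peak_table",
    "read_peak_table",
    "load_config",
    "config_hash",
    "builtin_peak_table",
]

_REQUIRED_KEYS = (
    "n_points",
    "spectral_width_hz",
    "spectrometer_freq_mhz",
    "nucleus",
    "ref_ppm",
    "provenance",
)

_NUCLEUS_TO_NIFTI = {Nucleus.P31: "31P", Nucleus.H1: "1H"}
_NIFTI_TO_NUCLEUS = {v: k for k, v in _NUCLEUS_TO_NIFTI.items()}


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_fid(
    fid: FIDSignal,
    path: str | Path,
    format: str = "columnar_text",
    extra: dict[str, object] | None = None,
) -> None:
    """Write a FID with its acquisition metadata.

    ``extra`` key/value pairs (e.g. the denoising parameters used) are
    carried in additional header lines.
    """
    if format == "nifti_mrs":
        _write_nifti_mrs(fid, path)
        return
    if format != "columnar_text":
        raise ValueError(f"unknown format {format!r}")
    acq = fid.acq
    lines = [
        f"# n_points: {acq.n_points}",
        f"# spectral_width_hz: {_fmt(acq.spectral_width)}",
        f"# spectrometer_freq_mhz: {_fmt(acq.spectrometer_freq)}",
        f"# nucleus: {acq.nucleus.value}",
        f"# ref_ppm: {_fmt(acq.ref_ppm)}",
        f"# provenance: {fid.provenance}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append("index,time_s,real,imag")
    t = acq.time_axis
    for i, (ti, s) in enumerate(zip(t, fid.samples)):
        lines.append(f"{i},{_fmt(ti)},{_fmt(s.real)},{_fmt(s.imag)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fid(path: str | Path, format: str = "columnar_text") -> FIDSignal:
    """Read a FID written by :func:`write_fid`; round-trips bit-exactly."""
    if format == "nifti_mrs":
        return _read_nifti_mrs(path)
    if format != "columnar_text":
        raise ValueError(f"unknown format {format!r}")
    header: dict[str, str] = {}
    rows: list[complex] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            elif line.startswith("index"):
                continue
            else:
                parts = line.split(",")
                rows.append(float(parts[2]) + 1j * float(parts[3]))
    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: missing header keys {missing}")
    n = int(header["n_points"])
    if len(rows) != n:
        raise ValueError(
            f"{path}: header declares n_points={n} but found {len(rows)} sample rows"
        )
    acq = AcquisitionParams(
        n_points=n,
        spectral_width=float(header["spectral_width_hz"]),
        spectrometer_freq=float(header["spectrometer_freq_mhz"]),
        nucleus=header["nucleus"],
        ref_ppm=float(header["ref_ppm"]),
    )
    return FIDSignal(np.asarray(rows), acq, provenance=header["provenance"])


def _write_nifti_mrs(fid: FIDSignal, path: str | Path) -> None:
    import nibabel as nib

    data = fid.samples.astype(np.complex64).reshape(1, 1, 1, -1)
    img = nib.Nifti2Image(data, affine=np.eye(4))
    img.header["pixdim"][4] = fid.acq.dwell_time
    meta = {
        "SpectrometerFrequency": [fid.acq.spectrometer_freq],
        "ResonantNucleus": [_NUCLEUS_TO_NIFTI[fid.acq.nucleus]],
        "hankelmrs_ref_ppm": fid.acq.ref_ppm,
        "hankelmrs_provenance": fid.provenance,
    }
    ext = nib.nifti1.Nifti1Extension(44, json.dumps(meta).encode())
    img.header.extensions.append(ext)
    nib.save(img, str(path))


def _read_nifti_mrs(path: str | Path) -> FIDSignal:
    import nibabel as nib

    img = nib.load(str(path))
    meta = None
    for ext in img.header.extensions:
        if ext.get_code() == 44:
            content = ext.get_content()
            if isinstance(content, bytes):
                content = content.decode()
            meta = json.loads(content)
    if meta is None:
        raise ValueError(f"{path}: no NIfTI-MRS (ecode 44) header extension")
    data = np.asarray(img.dataobj).reshape(-1)
    acq = AcquisitionParams(
        n_points=data.size,
        spectral_width=1.0 / float(img.header["pixdim"][4]),
        spectrometer_freq=float(meta["SpectrometerFrequency"][0]),
        nucleus=_NIFTI_TO_NUCLEUS[meta["ResonantNucleus"][0]],
        ref_ppm=float(meta.get("hankelmrs_ref_ppm", 0.0)),
    )
    return FIDSignal(data, acq, provenance=meta.get("hankelmrs_provenance", "raw"))


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """CSV with a ``# nucleus`` header and one row per resonance line."""
    lines = [f"# nucleus: {table.nucleus.value}", "metabolite,shift_ppm,amplitude,lw_hz,phase_deg"]
    for ln in table.lines:
        lines.append(
            f"{ln.metabolite},{_fmt(ln.shift_ppm)},{_fmt(ln.amplitude)},"
            f"{_fmt(ln.lw_hz)},{_fmt(ln.phase_deg)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_peak_table(path: str | Path) -> PeakTable:
    nucleus = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                if key.strip() == "nucleus":
                    nucleus = value.strip()
            elif line.startswith("metabolite"):
                continue
            else:
                name, shift, amp, lw, phase = line.split(",")
                rows.append(
                    ResonanceLine(name, float(shift), float(amp), float(lw), float(phase))
                )
    if nucleus is None:
        raise ValueError(f"{path}: missing '# nucleus:' header")
    return PeakTable(tuple(rows), nucleus)


def builtin_peak_table(name: str) -> PeakTable:
    """Built-in table by name: P31, H1 or H1_stroke."""
    if name == "H1_stroke":
        return stroke_peak_table()
    return default_peak_table(name)


# ---------------------------------------------------------------------------
# pipeline configuration

_SCHEMA = {
    "acquisition": {"n_points", "spectral_width_hz", "spectrometer_freq_mhz", "nucleus", "ref_ppm"},
    "peaks": {"builtin", "path"},
    "noise": {"sigma", "target_snr"},
    "denoise": {"rank", "window", "mode", "lb_hz"},
    "fit": {"window", "baseline_degree"},
    "experiment": {"n_replicates", "master_seed", "ratio_reference", "denoiser", "paired_noise"},
}


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"config section {section!r}: unknown keys {sorted(unknown)}")


def config_hash(raw: dict) -> str:
    """Stable hash of a parsed config (identical files -> identical hashes)."""
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path: str | Path) -> tuple[ExperimentConfig, dict]:
    """Parse and validate a YAML pipeline config.

    Returns the :class:`ExperimentConfig` plus the experiment section
    (n_replicates, master_seed defaults).  Unknown keys anywhere are
    rejected before any computation.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _check_keys("<top>", raw, set(_SCHEMA))
    for sec, allowed in _SCHEMA.items():
        if sec in raw and raw[sec] is not None:
            if not isinstance(raw[sec], dict):
                raise ValueError(f"config section {sec!r} must be a mapping")
            _check_keys(sec, raw[sec], allowed)

    peaks = raw.get("peaks") or {}
    if "path" in peaks:
        table = read_peak_table(peaks["path"])
    else:
        table = builtin_peak_table(peaks.get("builtin", "P31"))

    acq_sec = raw.get("acquisition") or {}
    base = default_acquisition(table.nucleus)
    acq = AcquisitionParams(
        n_points=int(acq_sec.get("n_points", base.n_points)),
        spectral_width=float(acq_sec.get("spectral_width_hz", base.spectral_width)),
        spectrometer_freq=float(
            acq_sec.get("spectrometer_freq_mhz", base.spectrometer_freq)
        ),
        nucleus=acq_sec.get("nucleus", base.nucleus),
        ref_ppm=float(acq_sec.get("ref_ppm", base.ref_ppm)),
    )

    den_sec = raw.get("denoise") or {}
    denoise = DenoiseParams(
        r=int(den_sec.get("rank", default_rank(acq.nucleus))),
        W=den_sec.get("window"),
        recon_mode=den_sec.get("mode", "concat"),
        lb_hz=float(den_sec.get("lb_hz", 0.0)),
    )

    fit_sec = raw.get("fit") or {}
    window = tuple(fit_sec["window"]) if "window" in fit_sec else None

    noise_sec = raw.get("noise") or {}
    exp_sec = raw.get("experiment") or {}
    config = ExperimentConfig(
        table=table,
        acq=acq,
        denoise=denoise,
        window=window,
        baseline_degree=int(fit_sec.get("baseline_degree", 2)),
        sigma=noise_sec.get("sigma"),
        target_snr=noise_sec.get("target_snr"),
        ratio_reference=exp_sec.get(
            "ratio_reference", "PCr" if acq.nucleus is Nucleus.P31 else None
        ),
        denoiser=exp_sec.get("denoiser", "lowrank"),
        paired_noise=bool(exp_sec.get("paired_noise", True)),
    )
    meta = {
        "n_replicates": int(exp_sec.get("n_replicates", 10)),
        "master_seed": int(exp_sec.get("master_seed", 0)),
        "config_hash": config_hash(raw),
    }
    return config, meta
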