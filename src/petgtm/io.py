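"""Volume I/O, run configuration and report writing.

Volumes are exchanged as NIfTI-1 (voxel spacing in the header; integer
data are read back as label volumes).  A minimal interfile reader is
included for interoperability with tomographic toolkits that exchange
``.hv``/``.v`` header + raw pairs; NIfTI remains the native format.
Experiment results are written as CSV tables plus a JSON summary and a
YAML config snapshot sufficient to reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .volumes import ActivityVolume, LabelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_interfile",
    "RunConfig",
    "write_report",
]


def write_volume(path, volume: ActivityVolume | LabelVolume) -> None:
    """Write a volume as NIfTI-1 with spacing and origin in the affine."""
    if isinstance(volume, LabelVolume):
        data = volume.labels.astype(np.int16)
    else:
        data = volume.values
    affine = np.diag(list(volume.voxel_size) + [1.0])
    # NIfTI affines address voxel centers; our origin is the grid corner
    affine[:3, 3] = np.asarray(volume.origin) + 0.5 * np.asarray(volume.voxel_size)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path) -> ActivityVolume | LabelVolume:
    """Read a NIfTI-1 volume; integer data comes back as a LabelVolume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing {zooms}")
    data = np.asanyarray(img.dataobj)
    origin = tuple(np.asarray(img.affine[:3, 3]) - 0.5 * np.asarray(zooms))
    if np.issubdtype(data.dtype, np.integer):
        return LabelVolume(data, tuple(float(z) for z in zooms), origin=origin)
    return ActivityVolume(data.astype(float), tuple(float(z) for z in zooms), origin)


def read_interfile(header_path) -> ActivityVolume:
    """Minimal interfile (.hv/.ah header + raw data) reader.

    Supports the common subset: little/big-endian float/short data,
    'matrix size' and 'scaling factor (mm/pixel)' per dimension.
    """
    header_path = Path(header_path)
    keys = {}
    for line in header_path.read_text().splitlines():
        if ":=" in line:
            k, _, v = line.partition(":=")
            keys[k.strip().lstrip("!").lower()] = v.strip()

    data_file = keys.get("name of data file")
    if not data_file:
        raise ValueError(f"{header_path}: no data file declared")
    data_path = header_path.parent / data_file

    ndim = int(keys.get("number of dimensions", 3))
    shape = [int(keys[f"matrix size [{i}]"]) for i in range(1, ndim + 1)]
    spacing = [
        float(keys.get(f"scaling factor (mm/pixel) [{i}]", 1.0)) for i in range(1, ndim + 1)
    ]
    fmt = keys.get("number format", "float")
    nbytes = int(keys.get("number of bytes per pixel", 4))
    byte_order = keys.get("imagedata byte order", "LITTLEENDIAN").upper()
    prefix = "<" if byte_order.startswith("LITTLE") else ">"
    dtype = {
        ("float", 4): "f4",
        ("float", 8): "f8",
        ("signed integer", 2): "i2",
        ("signed integer", 4): "i4",
        ("unsigned integer", 2): "u2",
    }.get((fmt, nbytes))
    if dtype is None:
        raise ValueError(f"{header_path}: unsupported number format {fmt}/{nbytes}")
    raw = np.fromfile(data_path, dtype=prefix + dtype)
    # interfile stores x fastest; our arrays are (x, y, z) C-ordered
    values = raw.reshape(shape[::-1]).transpose(range(ndim - 1, -1, -1)).astype(float)
    return ActivityVolume(values, tuple(spacing[:3]))


@dataclass
class RunConfig:
    """Serializable description of one evaluation run."""

    phantom: str = "spheres"
    methods: list[str] = field(default_factory=lambda: ["GTM", "sGTM", "GTMo", "sGTMo"])
    pet_shape: tuple[int, int, int] = (64, 64, 48)
    pet_voxel_mm: tuple[float, float, float] = (2.0, 2.0, 3.15)
    psf_fwhm_mm: tuple[float, float, float] = (7.23, 7.14, 6.65)
    noise_fraction: float = 0.25
    n_realizations: int = 50
    seed: int = 0
    filter_name: str = "hann"
    n_angles: int = 192
    unity_tol: float = 0.005
    outdir: str = "report"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for tup in ("pet_shape", "pet_voxel_mm", "psf_fwhm_mm"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for tup in ("pet_shape", "pet_voxel_mm", "psf_fwhm_mm"):
            data[tup] = list(data[tup])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_report(result, outdir, plots: bool = True) -> list[Path]:
    """Write an ExperimentResult as CSVs, JSON summary, config and plots.

    The config snapshot (with the master seed) is always written next to
    the tables, so any output directory can be reproduced exactly.
    Returns the list of files written.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write-probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    written = []

    def _csv(df, name):
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    _csv(result.rc, "rc.csv")
    if result.nmf is not None:
        _csv(result.nmf, "nmf.csv")
    if result.shift_curves is not None:
        _csv(result.shift_curves, "shift_curves.csv")

    snapshot = dict(result.config)
    snapshot["seed"] = result.seed
    snapshot["n_realizations"] = result.n_realizations
    p = outdir / "config.yaml"
    p.write_text(yaml.safe_dump(snapshot, sort_keys=False))
    written.append(p)

    p = outdir / "summary.json"
    p.write_text(json.dumps(snapshot, indent=2, sort_keys=True))
    written.append(p)

    if plots:
        written.extend(_write_plots(result, outdir))
    return written


def _write_plots(result, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    rc = result.rc.dropna(subset=["rc_mean"]) if result.rc is not None else None
    if rc is not None and len(rc):
        fig, ax = plt.subplots(figsize=(8, 4))
        labels = sorted(set(zip(rc.system, rc.region)))
        x = np.arange(len(labels))
        methods = list(dict.fromkeys(rc.method))
        width = 0.8 / max(len(methods), 1)
        for i, m in enumerate(methods):
            sub = rc[rc.method == m].set_index(["system", "region"])
            means = [sub.rc_mean.get(l, np.nan) for l in labels]
            stds = [sub.rc_std.get(l, 0.0) for l in labels]
            ax.bar(x + (i - len(methods) / 2) * width, means, width, yerr=stds, label=m)
        ax.axhline(1.0, color="g", lw=1)
        ax.set_xticks(x)
        ax.set_xticklabels([f"{s}:{r}" for s, r in labels], rotation=45, ha="right")
        ax.set_ylabel("recovery coefficient")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = outdir / "rc.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    if result.nmf is not None and len(result.nmf):
        fig, ax = plt.subplots(figsize=(8, 4))
        for m, sub in result.nmf.groupby("method"):
            ax.plot(
                [f"{s}:{r}" for s, r in zip(sub.system, sub.region)],
                sub.nmf,
                marker="o",
                label=m,
            )
        ax.axhline(1.0, color="g", lw=1)
        ax.set_ylabel("noise magnification factor")
        ax.tick_params(axis="x", rotation=45)
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = outdir / "nmf.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    if result.shift_curves is not None and len(result.shift_curves):
        fig, ax = plt.subplots(figsize=(7, 4))
        for (m, s, r), sub in result.shift_curves.groupby(["method", "system", "region"]):
            ax.plot(sub.shift_mm, sub.rc_norm, marker="o", label=f"{m} {s}:{r}")
        ax.axhline(1.0, color="g", lw=1)
        ax.set_xlabel("misregistration (mm)")
        ax.set_ylabel("normalized RC")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = outdir / "shift_curves.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
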