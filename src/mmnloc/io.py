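"""File formats: electrode files, HDF5 containers and TSV exports.

Electrode positions are whitespace-delimited text, one ``label x y z`` line
per sensor in metres; the ``.sfp`` dialect (centimetres) is auto-detected
from a header comment containing ``sfp`` or ``cm``.  Cohorts, ERPs and
leadfields travel in HDF5 containers; all tabular exports are TSV.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .forward import ElectrodeMontage, Leadfield, SourceGrid
from .synth import EpochSet, SubjectRecord
from .erp import Erp, MmnWave

__all__ = [
    "read_electrodes",
    "write_electrodes",
    "save_leadfield",
    "load_leadfield",
    "write_cohort",
    "iter_cohort_file",
    "cohort_manifest",
    "write_erps",
    "read_erps",
    "erp_to_tsv",
    "map_table",
    "load_bdf_epochs",
]


def read_electrodes(path) -> ElectrodeMontage:
    """Read a ``label x y z`` electrode file (metres; .sfp dialect in cm)."""
    labels, rows = [], []
    scale = 1.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                low = line.lower()
                if "sfp" in low or "cm" in low:
                    scale = 0.01
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed electrode line: {line!r}")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if str(path).endswith(".sfp"):
        scale = 0.01
    return ElectrodeMontage(
        labels=tuple(labels), positions=scale * np.asarray(rows, float)
    )


def write_electrodes(path, montage: ElectrodeMontage) -> None:
    with open(path, "w") as fh:
        fh.write("# electrode positions, metres\n")
        for lab, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"{lab} {x:.8f} {y:.8f} {z:.8f}\n")


def save_leadfield(path, L: Leadfield, grid: SourceGrid) -> None:
    """Grid + gain in one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=grid.points)
        f.create_dataset("gain", data=L.gain)
        f.create_dataset("tissue", data=np.char.encode(grid.tissue))
        f.create_dataset("region", data=np.char.encode(grid.region))
        f.attrs["spacing_mm"] = grid.spacing
        f.attrs["normalised"] = L.normalised
        f.attrs["grid_ref"] = L.grid_ref
        f.attrs["montage_ref"] = L.montage_ref


def load_leadfield(path) -> tuple[Leadfield, SourceGrid]:
    with h5py.File(path, "r") as f:
        pts = f["positions"][()]
        grid = SourceGrid(
            spacing=float(f.attrs["spacing_mm"]),
            points=pts,
            inside_mask=np.ones(pts.shape[0], bool),
            tissue=np.char.decode(f["tissue"][()]).astype("U16"),
            region=np.char.decode(f["region"][()]).astype("U16"),
            grid_id=str(f.attrs["grid_ref"]),
        )
        L = Leadfield(
            gain=f["gain"][()],
            normalised=bool(f.attrs["normalised"]),
            grid_ref=str(f.attrs["grid_ref"]),
            montage_ref=str(f.attrs["montage_ref"]),
        )
    return L, grid


# ---------------------------------------------------------------------------
# cohorts


def write_cohort(path, records, manifest_path=None) -> pd.DataFrame:
    """One HDF5 file for the whole cohort plus a manifest TSV.

    ``records`` may be any iterable of :class:`SubjectRecord`; it is consumed
    lazily so simulated cohorts can be streamed to disk.
    """
    rows = []
    with h5py.File(path, "w") as f:
        for rec in records:
            g = f.create_group(f"subjects/{rec.subject_id}")
            g.create_dataset("data", data=rec.epochs.data, compression="gzip")
            g.create_dataset(
                "condition", data=np.char.encode(rec.epochs.condition)
            )
            g.attrs["fs"] = rec.epochs.fs
            g.attrs["t0"] = rec.epochs.t0
            g.attrs["t1"] = rec.epochs.t1
            g.attrs["group"] = rec.group
            for k, v in rec.covariates.items():
                g.attrs[k] = v
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "age": rec.covariates.get("age", np.nan),
                    "speech_score": rec.covariates.get("speech_score", np.nan),
                    "cwit_inhib_switch_s": rec.covariates.get(
                        "cwit_inhib_switch_s", np.nan
                    ),
                }
            )
    manifest = pd.DataFrame(rows)
    if manifest_path is None:
        manifest_path = os.path.splitext(str(path))[0] + "_manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False, float_format="%.6g")
    return manifest


def iter_cohort_file(path):
    """Yield :class:`SubjectRecord` from a cohort HDF5, one subject at a time."""
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            g = f[f"subjects/{sid}"]
            epochs = EpochSet(
                data=g["data"][()],
                condition=np.char.decode(g["condition"][()]),
                fs=float(g.attrs["fs"]),
                t0=float(g.attrs["t0"]),
                t1=float(g.attrs["t1"]),
            )
            cov = {
                k: g.attrs[k]
                for k in ("age", "speech_score", "cwit_inhib_switch_s")
                if k in g.attrs
            }
            yield SubjectRecord(
                subject_id=sid,
                group=str(g.attrs["group"]),
                epochs=epochs,
                covariates=cov,
                true_gains={},
            )


def cohort_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# ERPs


def write_erps(path, entries) -> None:
    """``entries``: iterable of (subject_id, group, Erp, MmnWave)."""
    with h5py.File(path, "w") as f:
        for sid, group, erp, mmn in entries:
            g = f.create_group(f"subjects/{sid}")
            g.create_dataset("standard", data=erp.standard)
            g.create_dataset("deviant", data=erp.deviant)
            g.create_dataset("mmn", data=mmn.waveform)
            g.attrs["fs"] = erp.fs
            g.attrs["t0"] = erp.t0
            g.attrs["group"] = group
            g.attrs["n_standard"] = erp.n_trials_used["standard"]
            g.attrs["n_deviant"] = erp.n_trials_used["deviant"]


def read_erps(path):
    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            g = f[f"subjects/{sid}"]
            fs, t0 = float(g.attrs["fs"]), float(g.attrs["t0"])
            std = g["standard"][()]
            times = t0 + np.arange(std.shape[1]) * 1000.0 / fs
            erp = Erp(
                standard=std,
                deviant=g["deviant"][()],
                times=times,
                n_trials_used={
                    "standard": int(g.attrs["n_standard"]),
                    "deviant": int(g.attrs["n_deviant"]),
                },
                fs=fs,
                t0=t0,
            )
            mmn = MmnWave(waveform=g["mmn"][()], times=times, fs=fs, t0=t0)
            out.append((sid, str(g.attrs["group"]), erp, mmn))
    return out


def erp_to_tsv(path, waveform: np.ndarray, times: np.ndarray, labels) -> None:
    """Rows = samples, first column time_ms, then one column per channel."""
    df = pd.DataFrame(waveform.T, columns=list(labels))
    df.insert(0, "time_ms", times)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def map_table(
    grid: SourceGrid,
    P_std: np.ndarray,
    P_dev: np.ndarray,
    ratio_db: np.ndarray,
    defined: np.ndarray,
    method: str,
) -> pd.DataFrame:
    """Per-gridpoint map in the standard export schema."""
    return pd.DataFrame(
        {
            "x_mm": grid.points[:, 0],
            "y_mm": grid.points[:, 1],
            "z_mm": grid.points[:, 2],
            "region": grid.region,
            "P_std": P_std,
            "P_dev": P_dev,
            "ratio_dB": ratio_db,
            "defined": defined.astype(int),
            "method": method,
        }
    )


def write_subject_maps(path, method, subject_ids, groups, matrix, grid) -> None:
    """Per-subject ratio maps (subjects × grid points) for one method."""
    with h5py.File(path, "w") as f:
        f.create_dataset("ratio_db", data=np.asarray(matrix, float))
        f.create_dataset("subject_id", data=np.char.encode(np.asarray(subject_ids, "U16")))
        f.create_dataset("group", data=np.char.encode(np.asarray(groups, "U16")))
        f.create_dataset("positions", data=grid.points)
        f.create_dataset("region", data=np.char.encode(grid.region))
        f.attrs["method"] = method
        f.attrs["spacing_mm"] = grid.spacing


def read_subject_maps(path):
    with h5py.File(path, "r") as f:
        return {
            "method": str(f.attrs["method"]),
            "ratio_db": f["ratio_db"][()],
            "subject_id": np.char.decode(f["subject_id"][()]),
            "group": np.char.decode(f["group"][()]),
            "positions": f["positions"][()],
            "region": np.char.decode(f["region"][()]).astype("U16"),
        }


def load_bdf_epochs(raw_path, events_tsv, t0=-100.0, t1=500.0) -> EpochSet:
    """Epoch a BDF/EDF recording using an event table.

    ``events_tsv`` columns: ``trial onset_sample condition``.  Requires the
    optional :mod:`mne` dependency for the raw-file reader.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading BDF/EDF files requires the 'mne' package") from exc
    raw_path = str(raw_path)
    if raw_path.endswith(".bdf"):
        raw = mne.io.read_raw_bdf(raw_path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(raw_path, preload=True, verbose="error")
    fs = raw.info["sfreq"]
    sig = raw.get_data() * 1e6  # µV
    events = pd.read_csv(events_tsv, sep="\t")
    n_pre = int(round(-t0 * fs / 1000.0))
    n_post = int(round(t1 * fs / 1000.0))
    trials, conds = [], []
    for _, row in events.iterrows():
        s = int(row["onset_sample"])
        seg = sig[:, s - n_pre : s + n_post + 1]
        if seg.shape[1] != n_pre + n_post + 1:
            continue
        trials.append(seg)
        conds.append(str(row["condition"]))
    data = np.stack(trials)
    data -= data.mean(axis=1, keepdims=True)  # common average
    return EpochSet(data=data, condition=np.asarray(conds), fs=fs, t0=t0, t1=t1)
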