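"""On-disk containers: raw float32 matrix + JSON sidecar, cohort manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .recording import Recording
from .synth import GroundTruth

_DTYPE = np.float32


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write ``<path>.dat`` (float32, channel-major) + ``<path>.json``.

    ``path`` is the extension-less base name. Returns the sidecar path.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    recording.data.astype(_DTYPE).tofile(base.with_suffix(".dat"))
    meta = {
        "subject_id": recording.subject_id,
        "pair_id": recording.pair_id,
        "week": recording.week,
        "task": recording.task,
        "block": recording.block,
        "channel_names": list(recording.channel_names),
        "sampling_rate": recording.sampling_rate,
        "n_samples": recording.n_samples,
        "dtype": "float32",
    }
    sidecar = base.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises ``ValueError`` on a corrupt sidecar or when the matrix size does
    not factor into the sidecar's channel count.
    """
    base = Path(path)
    sidecar = base.with_suffix(".json")
    try:
        meta = json.loads(sidecar.read_text())
        n_ch = len(meta["channel_names"])
        n_samples = int(meta["n_samples"])
    except (json.JSONDecodeError, KeyError, TypeError) as err:
        raise ValueError(f"corrupt sidecar {sidecar}: {err}") from err
    flat = np.fromfile(base.with_suffix(".dat"), dtype=_DTYPE)
    if flat.size != n_ch * n_samples:
        raise ValueError(
            f"{base}.dat holds {flat.size} values; sidecar promises "
            f"{n_ch} channels x {n_samples} samples"
        )
    return Recording(
        subject_id=meta["subject_id"],
        pair_id=meta["pair_id"],
        week=meta["week"],
        task=meta["task"],
        block=meta.get("block", 1),
        channel_names=tuple(meta["channel_names"]),
        sampling_rate=meta["sampling_rate"],
        data=flat.reshape(n_ch, n_samples).astype(np.float64),
    )


def _recording_stem(rec: Recording) -> str:
    return f"sub{rec.subject_id:02d}_week{rec.week}_{rec.task}_b{rec.block}"


def write_cohort(
    recordings: Iterable[Recording], outdir: str | Path,
    ground_truth: GroundTruth | None = None,
) -> Path:
    """Write a stream of recordings plus a ``manifest.json`` index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        stem = _recording_stem(rec)
        write_recording(rec, outdir / stem)
        entries.append(
            {
                "path": stem,
                "subject_id": rec.subject_id,
                "week": rec.week,
                "task": rec.task,
                "block": rec.block,
            }
        )
    manifest: dict = {"recordings": entries}
    if ground_truth is not None:
        np.savez(
            outdir / "ground_truth.npz",
            freqs=ground_truth.freqs,
            scalp_channels=np.array(ground_truth.scalp_channels),
            **{f"profile_{s}": p for s, p in ground_truth.base_profiles.items()},
            **{f"template_{p}": t for p, t in ground_truth.pair_templates.items()},
            **{f"drift_{s}": d for s, d in ground_truth.drift.items()},
        )
        manifest["ground_truth"] = "ground_truth.npz"
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def iter_cohort_dir(cohort_dir: str | Path) -> Iterator[Recording]:
    """Stream recordings listed in a cohort directory's manifest."""
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    for entry in manifest["recordings"]:
        yield read_recording(cohort_dir / entry["path"])


def read_ground_truth(cohort_dir: str | Path) -> GroundTruth:
    cohort_dir = Path(cohort_dir)
    with np.load(cohort_dir / "ground_truth.npz") as z:
        profiles = {
            int(k.split("_")[1]): z[k] for k in z.files if k.startswith("profile_")
        }
        templates = {
            int(k.split("_")[1]): z[k] for k in z.files if k.startswith("template_")
        }
        drift = {int(k.split("_")[1]): z[k] for k in z.files if k.startswith("drift_")}
        return GroundTruth(
            freqs=z["freqs"],
            scalp_channels=tuple(z["scalp_channels"]),
            base_profiles=profiles,
            pair_templates=templates,
            drift=drift,
        )
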