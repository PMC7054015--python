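"""Trajectory and table I/O: extended XYZ ensembles with JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import Conformation, Ensemble

__all__ = ["write_ensemble", "read_ensemble"]

_TRAJ = "ensemble.xyz"
_MANIFEST = "manifest.json"


def write_ensemble(ensemble: Ensemble, out_dir: str | Path) -> Path:
    """Write an ensemble as extended XYZ plus a JSON manifest.

    One XYZ frame per conformation; the comment line carries
    ``key=value`` provenance (karyotype, replicate, sample index, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / _TRAJ, "w") as fh:
        for c in ensemble.conformations:
            fh.write(f"{len(c.positions)}\n")
            fh.write(
                f"karyotype={c.karyotype_name} replicate={c.replicate} "
                f"sample={c.sample_index} seed={c.seed}\n"
            )
            for x, y, z in c.positions:
                fh.write(f"C {x:.3f} {y:.3f} {z:.3f}\n")
    manifest = {
        "karyotype": ensemble.karyotype_name,
        "n_conformations": len(ensemble),
        "n_beads": int(len(ensemble.conformations[0].positions)) if len(ensemble) else 0,
        "provenance": ensemble.provenance,
    }
    with open(out / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def read_ensemble(in_dir: str | Path) -> Ensemble:
    """Read an ensemble written by :func:`write_ensemble`."""
    src = Path(in_dir)
    with open(src / _MANIFEST) as fh:
        manifest = json.load(fh)
    confs: list[Conformation] = []
    with open(src / _TRAJ) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            meta = dict(kv.split("=", 1) for kv in fh.readline().split())
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            confs.append(
                Conformation(
                    positions=pos,
                    karyotype_name=meta["karyotype"],
                    replicate=int(meta["replicate"]),
                    sample_index=int(meta["sample"]),
                    seed=int(meta["seed"]),
                )
            )
    return Ensemble(
        conformations=confs,
        karyotype_name=manifest["karyotype"],
        provenance=manifest.get("provenance", {}),
    )
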