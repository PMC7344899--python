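"""Trajectory/structure ingestion, campaign writers and the analysis pipeline.

Readers are thin wrappers over MDAnalysis: a structure (GRO/PDB) plus an
optional trajectory (XTC/TRR/DCD) and two atom selections — protein
backbone beads and lipid phosphate beads — yield the labelled frames the
contact metrics consume.  All coordinates are canonicalized to nm
(MDAnalysis reports Angstrom internally); boxes must be orthorhombic.

Outputs are tidy CSV tables plus a plain-text run log recording the seed,
parameter values, package versions and input digests.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import (
    DEFAULT_THRESHOLD_NM,
    ContactMatrix,
    LabeledFrame,
    MeltingCurve,
    NoTransitionError,
    contact_matrix,
    fit_melting_temperature,
    melting_curve,
    residue_contact_index,
    tagci,
)

__all__ = [
    "SelectionConfig",
    "load_labeled_frames",
    "write_campaign",
    "residue_index_table",
    "melting_curve_table",
    "write_run_log",
    "run_pipeline",
]

ANGSTROM_PER_NM = 10.0


@dataclass
class SelectionConfig:
    """Named bead selections plus the analysis knobs of one run."""

    backbone_selection: str = "name BB"
    phosphate_selection: str = "name PO4"
    threshold: float = DEFAULT_THRESHOLD_NM
    window: tuple[int, int] | None = None
    temperatures: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.backbone_selection or not self.phosphate_selection:
            raise ValueError("selections must be non-empty")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def _check_box(dims: np.ndarray, source: str) -> np.ndarray:
    if dims is None or np.all(dims[:3] == 0):
        raise ValueError(
            f"{source}: no box information; periodic minimum-image distances "
            "require an orthorhombic box"
        )
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise ValueError(f"{source}: triclinic box (angles {dims[3:6]}) not supported")
    return np.asarray(dims[:3], dtype=float) / ANGSTROM_PER_NM


def load_labeled_frames(
    structure_path: str | Path,
    trajectory_path: str | Path | None = None,
    selection: SelectionConfig | None = None,
) -> list[LabeledFrame]:
    """Read frames with backbone/phosphate selections, coordinates in nm."""
    import MDAnalysis as mda

    selection = selection or SelectionConfig()
    structure_path = Path(structure_path)
    if not structure_path.exists():
        raise FileNotFoundError(structure_path)
    if trajectory_path is not None:
        trajectory_path = Path(trajectory_path)
        if not trajectory_path.exists():
            raise FileNotFoundError(trajectory_path)
        u = mda.Universe(str(structure_path), str(trajectory_path))
    else:
        u = mda.Universe(str(structure_path))

    bb = u.select_atoms(selection.backbone_selection)
    ph = u.select_atoms(selection.phosphate_selection)
    for sel, grp, label in (
        (selection.backbone_selection, bb, "backbone"),
        (selection.phosphate_selection, ph, "phosphate"),
    ):
        if grp.n_atoms == 0:
            names = sorted(set(u.atoms.names))
            raise ValueError(
                f"{label} selection {sel!r} matched no atoms; "
                f"available atom names: {names}"
            )
    frames = []
    for ts in u.trajectory:
        box = _check_box(ts.dimensions, str(structure_path))
        frames.append(
            LabeledFrame(
                protein_backbone=bb.positions / ANGSTROM_PER_NM,
                phosphate_beads=ph.positions / ANGSTROM_PER_NM,
                box=box,
            )
        )
    return frames


def write_campaign(
    frames: Sequence[LabeledFrame],
    structure_path: str | Path,
    trajectory_path: str | Path | None = None,
    sequence: str | None = None,
) -> None:
    """Write frames as a GRO structure plus (optionally) an XTC trajectory.

    Backbone beads are written as BB atoms (one residue each, resnames from
    ``sequence`` where given); phosphates as PO4 atoms of LIP residues.
    """
    import MDAnalysis as mda

    first = frames[0]
    n_bb = first.protein_backbone.shape[0]
    n_ph = first.phosphate_beads.shape[0]
    n_atoms = n_bb + n_ph
    u = mda.Universe.empty(
        n_atoms, n_residues=n_bb + n_ph, atom_resindex=np.arange(n_atoms),
        residue_segindex=np.zeros(n_bb + n_ph, dtype=int), trajectory=True,
    )
    names = ["BB"] * n_bb + ["PO4"] * n_ph
    if sequence is not None and len(sequence) == n_bb:
        resnames = list(sequence) + ["LIP"] * n_ph
    else:
        resnames = ["PRO"] * n_bb + ["LIP"] * n_ph
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_bb + n_ph + 1))

    def coords(fr: LabeledFrame) -> np.ndarray:
        return np.vstack([fr.protein_backbone, fr.phosphate_beads]) * ANGSTROM_PER_NM

    def dims(fr: LabeledFrame) -> np.ndarray:
        return np.array([*(fr.box * ANGSTROM_PER_NM), 90.0, 90.0, 90.0])

    u.atoms.positions = coords(first)
    u.dimensions = dims(first)
    u.atoms.write(str(structure_path))
    if trajectory_path is not None:
        with mda.Writer(str(trajectory_path), n_atoms) as w:
            for fr in frames:
                u.atoms.positions = coords(fr)
                u.dimensions = dims(fr)
                w.write(u.atoms)


def residue_index_table(matrices: Mapping[float, ContactMatrix]) -> pd.DataFrame:
    """Tidy (residue, temperature, contact_index) table, 1-based residues."""
    rows = []
    for t in sorted(matrices):
        idx = residue_contact_index(matrices[t])
        for r, v in enumerate(idx, start=1):
            rows.append({"residue": r, "temperature": float(t), "contact_index": float(v)})
    return pd.DataFrame(rows)


def melting_curve_table(curve: MeltingCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "temperature": curve.temperatures,
            "gci": curve.global_contact_index,
            "segment_std": curve.segment_std,
        }
    )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


def write_run_log(
    path: str | Path,
    seed: int | None,
    parameters: dict,
    inputs: Sequence[str | Path] = (),
) -> None:
    """Plain-text run log: seed, parameters, package versions, input digests."""
    import MDAnalysis
    import scipy

    from . import __version__

    lines = [
        "cgmelt run log",
        f"seed: {seed}",
        f"python: {sys.version.split()[0]}",
        f"cgmelt: {__version__}",
        f"numpy: {np.__version__}",
        f"scipy: {scipy.__version__}",
        f"pandas: {pd.__version__}",
        f"MDAnalysis: {MDAnalysis.__version__}",
        f"parameters: {json.dumps(parameters, sort_keys=True, default=str)}",
    ]
    for p in inputs:
        p = Path(p)
        lines.append(f"input: {p} sha256:{_digest(p)}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PipelineResult:
    matrices: dict[float, ContactMatrix]
    curve: MeltingCurve
    tm: float | None
    outputs: list[Path] = field(default_factory=list)


def run_pipeline(
    frames_by_temperature: Mapping[float, Sequence[LabeledFrame]],
    out_dir: str | Path,
    selection: SelectionConfig | None = None,
    construct_name: str | None = None,
    seed: int | None = None,
    inputs: Sequence[str | Path] = (),
) -> PipelineResult:
    """Contact metrics -> melting curve -> Tm fit (-> TAGCI), written as CSV.

    Produces ``residue_contact_index.csv``, ``melting_curve.csv``,
    ``melting_fit.csv`` (when a transition exists), optionally
    ``tagci.csv``, and ``run.log``.
    """
    selection = selection or SelectionConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrices = {
        float(t): contact_matrix(list(fr), selection.threshold, float(t))
        for t, fr in frames_by_temperature.items()
    }
    outputs: list[Path] = []

    tab = residue_index_table(matrices)
    p = out_dir / "residue_contact_index.csv"
    tab.to_csv(p, index=False)
    outputs.append(p)

    curve = melting_curve(matrices, window=selection.window)
    p = out_dir / "melting_curve.csv"
    melting_curve_table(curve).to_csv(p, index=False)
    outputs.append(p)

    tm_value: float | None = None
    try:
        fit = fit_melting_temperature(curve)
        tm_value = fit.tm
        p = out_dir / "melting_fit.csv"
        pd.DataFrame(
            [
                {
                    "tm": fit.tm,
                    "tm_halfwidth": fit.tm_halfwidth,
                    "steepness": fit.steepness,
                    "high_plateau": fit.high_plateau,
                    "low_plateau": fit.low_plateau,
                    "residual_rms": fit.residual_rms,
                }
            ]
        ).to_csv(p, index=False)
        outputs.append(p)
    except NoTransitionError:
        pass  # flat or non-melting curve: curve CSV still written

    if construct_name is not None:
        res = tagci(matrices, construct_name)
        p = out_dir / "tagci.csv"
        pd.DataFrame(
            [
                {
                    "construct": res.construct_name,
                    "window_start": res.window_start,
                    "window_len": res.window_len,
                    "tagci": res.value,
                }
            ]
        ).to_csv(p, index=False)
        outputs.append(p)

    write_run_log(
        out_dir / "run.log",
        seed,
        {
            "threshold": selection.threshold,
            "window": selection.window,
            "temperatures": sorted(matrices),
            "construct": construct_name,
        },
        inputs,
    )
    outputs.append(out_dir / "run.log")
    return PipelineResult(matrices=matrices, curve=curve, tm=tm_value, outputs=outputs)
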