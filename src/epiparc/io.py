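"""Artifact readers/writers and experiment configuration.

Every artifact round-trips losslessly and carries a versioned header;
malformed files raise descriptive parse errors rather than failing silently.

Cohort directory layout::

    cohort/
      manifest.json                  generator params + seeds
      graph/edges.txt                one "u v" pair per line
      graph/vertices.csv             vertex, hemisphere (L/R), mask (0/1)
      truth/group_labels.txt         one integer per vertex (0 = masked)
      truth/subject-<s>_labels.txt
      truth/lut.txt                  FreeSurfer-style: index name R G B A
      truth/mu_true.csv
      runs/sub-<s>_ses-<t>.npz       vertex_ts, roi_ts, tr_seconds
      designs/sub-<s>_design.csv     onset, duration, kind
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTruth, RunTimeSeries, StimulationDesign
from .graph import HEMI_L, HEMI_R, CorticalGraph
from .mshbm import MSHBMParams
from .profiles import ConnectivityProfile

FORMAT_VERSION = "epiparc-v1"


class ArtifactError(ValueError):
    """Malformed or version-mismatched artifact file."""


# --------------------------------------------------------------------------
# configuration

@dataclasses.dataclass
class ExperimentConfig:
    """Full experiment configuration; every stochastic stage derives its
    seed deterministically from ``root_seed``."""

    # cohort geometry
    n_per_hemisphere: int = 300
    topology: str = "grid"
    K: int = 5
    R: int = 50
    # cohort composition
    n_train_subjects: int = 5
    n_train_runs: int = 2
    dominance_design: dict = dataclasses.field(
        default_factory=lambda: {"left": 15, "bilateral": 14, "right": 14})
    n_test_runs: int = 2
    n_eval_subjects: int = 14     # test subjects entering the six-way comparison
    # signal model
    T: int = 200
    snr: float = 4.0
    deviation_rate: float = 0.1
    top_fraction: float = 0.10
    # stimulation arm
    stim_blocks: int = 8
    frames_per_block: int = 15
    discard_frames: int = 4
    stim_networks: tuple = (1,)
    stim_effect: float = 2.0
    # model hyperparameters
    c: float = 1.0
    n_init: int = 3
    vmf_max_iter: int = 100
    train_max_iter: int = 10
    infer_max_iter: int = 30
    # bookkeeping
    root_seed: int = 0
    out_dir: str = "epiparc_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stim_networks"] = list(self.stim_networks)
        d["format_version"] = FORMAT_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d.pop("format_version", None)
        if "stim_networks" in d:
            d["stim_networks"] = tuple(d["stim_networks"])
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ArtifactError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        path = Path(path)
        try:
            with open(path) as fh:
                d = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        except (json.JSONDecodeError, yaml.YAMLError) as e:
            raise ArtifactError(f"cannot parse config {path}: {e}") from e
        if not isinstance(d, dict):
            raise ArtifactError(f"config {path} is not a mapping")
        return cls.from_dict(d)


# --------------------------------------------------------------------------
# graph

def write_graph(graph: CorticalGraph, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "edges.txt", "w") as fh:
        fh.write(f"# {FORMAT_VERSION} edges\n")
        for u, v in graph.edges:
            fh.write(f"{u} {v}\n")
    hemi = np.where(graph.hemisphere == HEMI_L, "L", "R")
    pd.DataFrame({"vertex": np.arange(graph.n_vertices),
                  "hemisphere": hemi,
                  "mask": graph.cortex_mask.astype(int)}
                 ).to_csv(directory / "vertices.csv", index=False)


def read_graph(directory) -> CorticalGraph:
    directory = Path(directory)
    epath = directory / "edges.txt"
    try:
        lines = epath.read_text().splitlines()
    except OSError as e:
        raise ArtifactError(f"cannot read {epath}: {e}") from e
    if not lines or FORMAT_VERSION not in lines[0]:
        raise ArtifactError(f"{epath}:1: missing/mismatched format header")
    edges = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2 or not all(p.isdigit() for p in parts):
            raise ArtifactError(f"{epath}:{i}: expected 'u v', got {line!r}")
        edges.append((int(parts[0]), int(parts[1])))
    vdf = pd.read_csv(directory / "vertices.csv")
    for col in ("vertex", "hemisphere", "mask"):
        if col not in vdf.columns:
            raise ArtifactError(f"vertices.csv: missing column {col!r}")
    hemi = np.where(vdf["hemisphere"].to_numpy() == "L", HEMI_L, HEMI_R)
    return CorticalGraph(len(vdf), np.array(edges), hemi,
                         vdf["mask"].to_numpy().astype(bool))


# --------------------------------------------------------------------------
# time series and designs

def write_run(run: RunTimeSeries, path) -> None:
    np.savez_compressed(path, version=FORMAT_VERSION,
                        subject_id=run.subject_id, session_id=run.session_id,
                        vertex_ts=run.vertex_ts, roi_ts=run.roi_ts,
                        tr_seconds=run.tr_seconds)


def read_run(path) -> RunTimeSeries:
    try:
        with np.load(path) as z:
            if str(z["version"]) != FORMAT_VERSION:
                raise ArtifactError(f"{path}: format version mismatch")
            return RunTimeSeries(int(z["subject_id"]), int(z["session_id"]),
                                 z["vertex_ts"], z["roi_ts"], float(z["tr_seconds"]))
    except ArtifactError:
        raise
    except (OSError, KeyError, ValueError, zipfile_error()) as e:
        raise ArtifactError(f"cannot read run {path}: {e}") from e


def zipfile_error():
    import zipfile
    return zipfile.BadZipFile


def write_design(design: StimulationDesign, path) -> None:
    df = pd.DataFrame({"onset": design.block_onsets,
                       "duration": design.block_durations,
                       "kind": design.block_kinds})
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} design discard_frames={design.discard_frames}\n")
        df.to_csv(fh, index=False)


def read_design(path) -> StimulationDesign:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or FORMAT_VERSION not in lines[0]:
        raise ArtifactError(f"{path}:1: missing/mismatched format header")
    try:
        discard = int(lines[0].rsplit("discard_frames=", 1)[1])
        df = pd.read_csv(path, comment="#")
        return StimulationDesign(df["onset"].to_numpy(), df["duration"].to_numpy(),
                                 list(df["kind"]), discard)
    except (IndexError, KeyError, ValueError) as e:
        raise ArtifactError(f"cannot parse design {path}: {e}") from e


# --------------------------------------------------------------------------
# profiles (sparse triplet text)

def write_profile(profile: ConnectivityProfile, path) -> None:
    rows, cols = np.nonzero(profile.matrix)
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} profile subject={profile.subject_id} "
                 f"session={profile.session_id} V={profile.V} R={profile.R} "
                 f"top_fraction={profile.top_fraction} n_kept={profile.n_kept}\n")
        for v, r in zip(rows, cols):
            fh.write(f"{v} {r} {float(profile.matrix[v, r])!r}\n")


def read_profile(path) -> ConnectivityProfile:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or FORMAT_VERSION not in lines[0]:
        raise ArtifactError(f"{path}:1: missing/mismatched format header")
    try:
        header = dict(tok.split("=") for tok in lines[0].split()[3:])
        V, R = int(header["V"]), int(header["R"])
        mat = np.zeros((V, R))
        for i, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            v, r, val = line.split()
            mat[int(v), int(r)] = float(val)
        return ConnectivityProfile(int(header["subject"]), int(header["session"]),
                                   mat, float(header["top_fraction"]),
                                   int(header["n_kept"]))
    except (KeyError, ValueError, IndexError) as e:
        raise ArtifactError(f"cannot parse profile {path}: {e}") from e


# --------------------------------------------------------------------------
# parcellations

_DEFAULT_RGBA = (128, 128, 128, 255)


def write_parcellation(labels: np.ndarray, K: int, path_labels, path_lut,
                       names: list | None = None) -> None:
    labels = np.asarray(labels, dtype=int)
    with open(path_labels, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} labels K={K} V={len(labels)}\n")
        fh.writelines(f"{int(v)}\n" for v in labels)
    names = names or [f"Network{k}" for k in range(1, K + 1)]
    with open(path_lut, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} lut\n")
        fh.write("0 Unassigned 0 0 0 0\n")
        for k, name in enumerate(names, start=1):
            r, g, b, a = _DEFAULT_RGBA
            fh.write(f"{k} {name} {r} {g} {b} {a}\n")


def read_parcellation(path_labels, path_lut=None) -> tuple[np.ndarray, int, list]:
    path_labels = Path(path_labels)
    lines = path_labels.read_text().splitlines()
    if not lines or FORMAT_VERSION not in lines[0]:
        raise ArtifactError(f"{path_labels}:1: missing/mismatched format header")
    try:
        header = dict(tok.split("=") for tok in lines[0].split()[3:])
        K, V = int(header["K"]), int(header["V"])
    except (KeyError, ValueError) as e:
        raise ArtifactError(f"{path_labels}:1: bad header: {e}") from e
    body = [line for line in lines[1:] if line.strip()]
    if len(body) != V:
        raise ArtifactError(f"{path_labels}: expected {V} labels, found {len(body)}")
    try:
        labels = np.array([int(x) for x in body])
    except ValueError as e:
        raise ArtifactError(f"{path_labels}: non-integer label: {e}") from e
    if labels.max(initial=0) > K or labels.min(initial=0) < 0:
        raise ArtifactError(f"{path_labels}: labels outside 0..K")
    names = [f"Network{k}" for k in range(1, K + 1)]
    if path_lut is not None:
        lut_lines = [ln for ln in Path(path_lut).read_text().splitlines()
                     if ln.strip() and not ln.startswith("#")]
        entries = [ln.split() for ln in lut_lines]
        if len(entries) != K + 1:
            raise ArtifactError(f"{path_lut}: LUT has {len(entries) - 1} networks, "
                                f"labels file declares K={K}")
        names = [e[1] for e in entries[1:]]
    return labels, K, names


# --------------------------------------------------------------------------
# model container

def write_model(params: MSHBMParams, path) -> None:
    meta = json.dumps({"format_version": FORMAT_VERSION, "K": params.K,
                       "R": params.R, "V": params.V, "c": params.c,
                       "trained_on": params.trained_on})
    np.savez_compressed(path, meta=meta, mu=params.mu, epsilon=params.epsilon,
                        sigma=params.sigma, kappa=params.kappa,
                        theta=params.theta,
                        objective_path=params.objective_path
                        if params.objective_path is not None else np.zeros(0))


def read_model(path) -> MSHBMParams:
    try:
        with np.load(path) as z:
            meta = json.loads(str(z["meta"]))
            if meta.get("format_version") != FORMAT_VERSION:
                raise ArtifactError(f"{path}: format version mismatch")
            return MSHBMParams(mu=z["mu"], epsilon=z["epsilon"], sigma=z["sigma"],
                               kappa=float(z["kappa"]), theta=z["theta"],
                               c=float(meta["c"]), K=int(meta["K"]),
                               R=int(meta["R"]), V=int(meta["V"]),
                               trained_on=meta["trained_on"],
                               objective_path=z["objective_path"])
    except ArtifactError:
        raise
    except (OSError, KeyError, ValueError, json.JSONDecodeError, zipfile_error()) as e:
        raise ArtifactError(f"cannot read model {path}: {e}") from e


# --------------------------------------------------------------------------
# cohort directories

def write_cohort(truth: CohortTruth, runs: dict, directory) -> None:
    directory = Path(directory)
    write_graph(truth.graph, directory / "graph")
    tdir = directory / "truth"
    tdir.mkdir(parents=True, exist_ok=True)
    write_parcellation(truth.group_labels, truth.K,
                       tdir / "group_labels.txt", tdir / "lut.txt")
    for s, lab in enumerate(truth.subject_labels):
        write_parcellation(lab, truth.K, tdir / f"subject-{s}_labels.txt",
                           tdir / "lut.txt")
    pd.DataFrame(truth.mu_true).to_csv(tdir / "mu_true.csv", index=False)
    rdir = directory / "runs"
    rdir.mkdir(exist_ok=True)
    for (s, t), run in runs.items():
        write_run(run, rdir / f"sub-{s}_ses-{t}.npz")
    manifest = {
        "format_version": FORMAT_VERSION,
        "K": truth.K, "R": truth.R,
        "language_ids": [int(x) for x in truth.language_ids],
        "roi_parents": [int(x) for x in truth.roi_parents],
        "dominance": truth.dominance,
        "target_li": [None if not np.isfinite(x) else float(x) for x in truth.target_li],
        "achieved_li": [None if not np.isfinite(x) else float(x) for x in truth.achieved_li],
        "li_flagged": truth.li_flagged,
        "generator_params": truth.generator_params,
        "run_keys": sorted([list(k) for k in runs]),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_cohort(directory) -> tuple[CohortTruth, dict]:
    directory = Path(directory)
    try:
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
    except (OSError, json.JSONDecodeError) as e:
        raise ArtifactError(f"cannot read cohort manifest: {e}") from e
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ArtifactError("cohort manifest: format version mismatch")
    graph = read_graph(directory / "graph")
    tdir = directory / "truth"
    group_labels, K, _ = read_parcellation(tdir / "group_labels.txt", tdir / "lut.txt")
    mu_true = pd.read_csv(tdir / "mu_true.csv").to_numpy()
    n_subjects = len(manifest["dominance"]) if manifest["dominance"] else \
        len(list(tdir.glob("subject-*_labels.txt")))
    subject_labels = [read_parcellation(tdir / f"subject-{s}_labels.txt")[0]
                      for s in range(n_subjects)]
    truth = CohortTruth(
        graph=graph, K=K, R=mu_true.shape[1], group_labels=group_labels,
        mu_true=mu_true, roi_parents=np.array(manifest["roi_parents"]),
        language_ids=tuple(manifest["language_ids"]),
        subject_labels=subject_labels,
        dominance=manifest["dominance"],
        target_li=[np.nan if x is None else x for x in manifest["target_li"]],
        achieved_li=[np.nan if x is None else x for x in manifest["achieved_li"]],
        li_flagged=manifest["li_flagged"],
        generator_params=manifest["generator_params"])
    runs = {}
    for s, t in manifest["run_keys"]:
        runs[(s, t)] = read_run(directory / "runs" / f"sub-{s}_ses-{t}.npz")
    return truth, runs
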