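"""HDF5 / CSV / OFF readers and writers shared by all stages.

One HDF5 container per artifact kind:

* geometry:   /positions (m,3), /triangles (n_tri,3), /adjacency (m,m),
              /gain (n,m), /electrode_positions (n,3)
* basis:      /eigenvalues (m,), /eigenvectors (m,m),
              /graph_frequencies (m,), /k (scalar)
* dataset:    /samples/<id>/{s_true,x_clean,x_noisy,centers,members_<j>},
              /split/{train,val,test}; generation config as a YAML string
              attribute "config"
* checkpoint: all BiLSTM weight arrays, standardizer arrays, config YAML,
              and the spectral-basis fingerprint guarding against
              basis/model mismatch

Meshes can additionally round-trip through the plain-text OFF format, and
real EEG enters through :func:`load_eeg_matrix` (HDF5 or CSV, channels x
samples with a sampling-rate attribute/header).
"""

from __future__ import annotations

import numpy as np
import h5py
import yaml

from .bilstm import BiLSTMModel, BiLSTMRegressor, LSTMCellParams, Standardizer
from .simulate import Dataset, PatchSpec, SimSample
from .spectral import SpectralBasis
from .source_space import LeadField, SourceGraph, SourceSpace

__all__ = [
    "save_geometry",
    "load_geometry",
    "save_basis",
    "load_basis",
    "spectrum_to_csv",
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "write_off",
    "read_off",
    "load_eeg_matrix",
    "save_eeg_matrix",
]


# ---------------------------------------------------------------- geometry

def save_geometry(
    path,
    space: SourceSpace,
    graph: SourceGraph | None = None,
    leadfield: LeadField | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=space.positions)
        f.create_dataset("triangles", data=space.triangles)
        if graph is not None:
            f.create_dataset("adjacency", data=graph.adjacency)
            f.attrs["neighbor_order"] = graph.neighbor_order
        if leadfield is not None:
            f.create_dataset("gain", data=leadfield.gain)
            f.create_dataset("electrode_positions", data=leadfield.electrode_positions)


def load_geometry(
    path,
) -> tuple[SourceSpace, SourceGraph | None, LeadField | None]:
    with h5py.File(path, "r") as f:
        space = SourceSpace(positions=f["positions"][()], triangles=f["triangles"][()])
        graph = None
        if "adjacency" in f:
            graph = SourceGraph(
                adjacency=f["adjacency"][()],
                neighbor_order=int(f.attrs.get("neighbor_order", 1)),
            )
        leadfield = None
        if "gain" in f:
            leadfield = LeadField(
                gain=f["gain"][()],
                electrode_positions=f["electrode_positions"][()],
            )
    return space, graph, leadfield


# ------------------------------------------------------------------- basis

def save_basis(path, basis: SpectralBasis) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eigenvalues", data=basis.eigenvalues)
        f.create_dataset("eigenvectors", data=basis.eigenvectors)
        if basis.graph_frequencies is not None:
            f.create_dataset("graph_frequencies", data=basis.graph_frequencies)
        f.create_dataset("k", data=basis.k if basis.k is not None else basis.m)
        if basis.t_f is not None:
            f.attrs["t_f"] = basis.t_f


def load_basis(path) -> SpectralBasis:
    with h5py.File(path, "r") as f:
        return SpectralBasis(
            eigenvalues=f["eigenvalues"][()],
            eigenvectors=f["eigenvectors"][()],
            k=int(f["k"][()]),
            t_f=float(f.attrs["t_f"]) if "t_f" in f.attrs else None,
            graph_frequencies=(
                f["graph_frequencies"][()] if "graph_frequencies" in f else None
            ),
        )


def spectrum_to_csv(path, basis: SpectralBasis) -> None:
    """CSV of (eigenvalue, graph frequency) pairs for spectrum plots."""
    if basis.graph_frequencies is None:
        raise ValueError("graph frequencies not computed; call graph_frequency first")
    arr = np.column_stack([basis.eigenvalues, basis.graph_frequencies])
    np.savetxt(
        path, arr, delimiter=",", header="eigenvalue,graph_frequency", comments=""
    )


# ----------------------------------------------------------------- dataset

def save_dataset(path, dataset: Dataset) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = yaml.safe_dump(dataset.config)
        grp_split = f.create_group("split")
        for name, idx in dataset.split.items():
            grp_split.create_dataset(name, data=np.asarray(idx, dtype=np.int64))
        grp = f.create_group("samples")
        for i, s in enumerate(dataset.samples):
            g = grp.create_group(str(i))
            g.create_dataset("s_true", data=s.s_true)
            g.create_dataset("x_clean", data=s.x_clean)
            g.create_dataset("x_noisy", data=s.x_noisy)
            g.create_dataset("centers", data=np.asarray(s.patch.centers, np.int64))
            for j, mem in enumerate(s.patch.members):
                g.create_dataset(f"members_{j}", data=np.asarray(mem, np.int64))
            g.attrs["snr_db"] = s.snr_db
            g.attrs["fs_hz"] = s.fs_hz
            g.attrs["seed"] = s.seed
            g.attrs["neighbor_scale"] = s.patch.neighbor_scale


def load_dataset(path) -> Dataset:
    with h5py.File(path, "r") as f:
        config = yaml.safe_load(f.attrs["config"])
        split = {name: f["split"][name][()] for name in f["split"]}
        samples = []
        ids = sorted(f["samples"], key=int)
        for i in ids:
            g = f["samples"][i]
            centers = [int(c) for c in g["centers"][()]]
            members = [
                g[f"members_{j}"][()] for j in range(len(centers))
            ]
            patch = PatchSpec(
                centers=centers,
                members=members,
                neighbor_scale=float(g.attrs["neighbor_scale"]),
            )
            samples.append(
                SimSample(
                    s_true=g["s_true"][()],
                    x_clean=g["x_clean"][()],
                    x_noisy=g["x_noisy"][()],
                    patch=patch,
                    snr_db=float(g.attrs["snr_db"]),
                    fs_hz=float(g.attrs["fs_hz"]),
                    seed=int(g.attrs["seed"]),
                )
            )
    return Dataset(samples=samples, split=split, config=config)


# -------------------------------------------------------------- checkpoint

_CELL_FIELDS = ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o")


def save_checkpoint(
    path,
    regressor: BiLSTMRegressor,
    basis: SpectralBasis | None = None,
    config: dict | None = None,
) -> None:
    """Persist a trained regressor (weights + standardizers + config) and
    the fingerprint of the basis it was trained against."""
    model = regressor.model_
    with h5py.File(path, "w") as f:
        for prefix, cell in (
            ("forward", model.forward_cell),
            ("backward", model.backward_cell),
        ):
            g = f.create_group(prefix)
            for name in _CELL_FIELDS:
                g.create_dataset(name, data=getattr(cell, name))
        f.create_dataset("W_s", data=model.W_s)
        f.create_dataset("b_s", data=model.b_s)
        f.attrs["output_activation"] = model.output_activation
        f.attrs["params"] = yaml.safe_dump(regressor.get_params())
        if config:
            f.attrs["config"] = yaml.safe_dump(config)
        if basis is not None:
            f.attrs["basis_fingerprint"] = basis.fingerprint()
        for label, scaler in (
            ("input_scaler", regressor.input_scaler_),
            ("target_scaler", regressor.target_scaler_),
        ):
            if scaler is not None:
                g = f.create_group(label)
                g.create_dataset("mean", data=scaler.mean)
                g.create_dataset("std", data=scaler.std)
                g.create_dataset("zero_variance", data=scaler.zero_variance)


def load_checkpoint(path, basis: SpectralBasis | None = None) -> BiLSTMRegressor:
    """Rebuild a fitted regressor; if ``basis`` is given, its fingerprint
    must match the one stored at save time."""
    with h5py.File(path, "r") as f:
        if basis is not None and "basis_fingerprint" in f.attrs:
            if f.attrs["basis_fingerprint"] != basis.fingerprint():
                raise ValueError(
                    "checkpoint was trained against a different spectral basis "
                    "(fingerprint mismatch)"
                )
        cells = {}
        for prefix in ("forward", "backward"):
            g = f[prefix]
            cells[prefix] = LSTMCellParams(
                **{name: g[name][()] for name in _CELL_FIELDS}
            )
        model = BiLSTMModel(
            forward_cell=cells["forward"],
            backward_cell=cells["backward"],
            W_s=f["W_s"][()],
            b_s=f["b_s"][()],
            output_activation=str(f.attrs["output_activation"]),
        )
        reg = BiLSTMRegressor(**yaml.safe_load(f.attrs["params"]))
        scalers = {}
        for label in ("input_scaler", "target_scaler"):
            if label in f:
                g = f[label]
                scalers[label] = Standardizer(
                    mean=g["mean"][()],
                    std=g["std"][()],
                    zero_variance=g["zero_variance"][()].astype(bool),
                )
            else:
                scalers[label] = None
    reg.model_ = model
    reg.input_scaler_ = scalers["input_scaler"]
    reg.target_scaler_ = scalers["target_scaler"]
    reg.history_ = []
    # rebuild the stacked parameter list used by predict; training runs in
    # float32, so cast back for bit-identical predictions after reload
    wf, bf = model.forward_cell.stacked()
    wb, bb = model.backward_cell.stacked()
    reg._params_ = [
        np.asarray(p, dtype=np.float32)
        for p in (wf, bf, wb, bb, model.W_s, model.b_s)
    ]
    return reg


# --------------------------------------------------------------------- OFF

def write_off(path, space: SourceSpace) -> None:
    """Write the mesh in ASCII OFF format."""
    with open(path, "w") as f:
        f.write("OFF\n")
        f.write(f"{space.m} {len(space.triangles)} 0\n")
        for p in space.positions:
            f.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        for t in space.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_off(path) -> SourceSpace:
    with open(path) as f:
        tokens = []
        for line in f:
            line = line.split("#")[0].strip()
            if line:
                tokens.extend(line.split())
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    cursor = 4
    pos = np.array(tokens[cursor : cursor + 3 * nv], dtype=float).reshape(nv, 3)
    cursor += 3 * nv
    tris = []
    for _ in range(nf):
        cnt = int(tokens[cursor])
        if cnt != 3:
            raise ValueError("only triangular faces are supported")
        tris.append([int(t) for t in tokens[cursor + 1 : cursor + 4]])
        cursor += cnt + 1
    return SourceSpace(positions=pos, triangles=np.array(tris, dtype=np.int64))


# --------------------------------------------------------------------- EEG

def save_eeg_matrix(path, x: np.ndarray, fs_hz: float) -> None:
    """Write an EEG matrix (channels x samples); HDF5 (dataset /eeg with an
    ``fs`` attribute) or CSV (header line ``# fs=<rate>``) by extension."""
    x = np.asarray(x, dtype=float)
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("eeg", data=x)
            d.attrs["fs"] = fs_hz
    else:
        np.savetxt(path, x, delimiter=",", header=f"fs={fs_hz:g}")


def load_eeg_matrix(path, leadfield: LeadField | None = None):
    """Load an EEG matrix; returns (array (n, T), fs_hz).  If a lead field
    is given, the channel count must match its electrode count."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            x = f["eeg"][()]
            fs = float(f["eeg"].attrs["fs"])
    else:
        fs = None
        with open(path) as f:
            first = f.readline().strip()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("fs=")[1])
        if fs is None:
            raise ValueError("CSV is missing the '# fs=<rate>' header line")
        x = np.loadtxt(path, delimiter=",", comments="#")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("EEG matrix has non-finite entries")
    if leadfield is not None and x.shape[0] != leadfield.n:
        raise ValueError(
            f"EEG has {x.shape[0]} channels but the lead field has "
            f"{leadfield.n} electrodes"
        )
    return x, fs
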