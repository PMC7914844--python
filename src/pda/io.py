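"""Readers and writers: HDF5 archives, YAML reports, extended XYZ.

Archive layouts (HDF5):

samples archive
    datasets ``positions`` (N, n, 3) and ``spins`` (n,);
    attrs ``seed``, ``model``, ``acceptance_ratio``, ``step``,
    ``burn_in``, ``thinning``, ``walkers``.

maxima archive
    datasets ``positions`` (M, n, 3), ``values`` (M,), ``counts`` (M,),
    ``frozen`` (M, n), ``spins`` (n,);
    attrs ``model``, ``n_total_samples``.

Both are self-describing, so externally produced samples or maxima can
be imported for (re-)clustering.
"""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .clustering import Cluster, nucleus_electron_counts
from .configurations import ElectronConfiguration
from .errors import ArchiveError, ContractError
from .geometry import MoleculeGeometry, read_xyz
from .maximization import Maximum
from .motifs import DotStructure
from .sampling import SampleSet
from .wavefunctions import (
    DensityModel,
    GaussianMixtureDensity,
    STOrbital,
    SlaterDeterminantDensity,
    build_h2_cas,
    build_h2_hartree_fock,
)


# ------------------------------------------------------------------- archives
def write_sample_archive(path: str | Path, samples: SampleSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=samples.positions)
        f.create_dataset("spins", data=samples.spins)
        f.attrs["seed"] = samples.seed
        f.attrs["model"] = samples.model_id
        f.attrs["acceptance_ratio"] = samples.acceptance_ratio
        f.attrs["step"] = samples.step
        f.attrs["burn_in"] = samples.burn_in
        f.attrs["thinning"] = samples.thinning
        f.attrs["walkers"] = samples.walkers


def read_sample_archive(path: str | Path) -> SampleSet:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ArchiveError(f"cannot open sample archive {path}: {exc}") from exc
    with f:
        for key in ("positions", "spins"):
            if key not in f:
                raise ArchiveError(f"sample archive {path} missing dataset {key!r}")
        positions = np.asarray(f["positions"])
        spins = np.asarray(f["spins"])
        if positions.ndim != 3 or positions.shape[1] != len(spins):
            raise ArchiveError(
                f"sample archive {path}: positions {positions.shape} do not "
                f"match {len(spins)} spins"
            )
        return SampleSet(
            positions=positions,
            spins=spins,
            seed=int(f.attrs.get("seed", -1)),
            model_id=str(f.attrs.get("model", "unknown")),
            acceptance_ratio=float(f.attrs.get("acceptance_ratio", 0.5)),
            step=float(f.attrs.get("step", 0.0)),
            burn_in=int(f.attrs.get("burn_in", 0)),
            thinning=int(f.attrs.get("thinning", 1)),
            walkers=int(f.attrs.get("walkers", 1)),
        )


def write_maxima_archive(
    path: str | Path,
    maxima: list[Maximum],
    model_id: str,
    n_total_samples: int,
) -> None:
    if not maxima:
        raise ContractError("refusing to write an empty maxima archive")
    spins = maxima[0].configuration.spins
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "positions", data=np.stack([m.configuration.positions for m in maxima])
        )
        f.create_dataset("values", data=np.array([m.value for m in maxima]))
        f.create_dataset("counts", data=np.array([m.count for m in maxima]))
        f.create_dataset("frozen", data=np.stack([m.frozen for m in maxima]))
        f.create_dataset("spins", data=spins)
        f.attrs["model"] = model_id
        f.attrs["n_total_samples"] = n_total_samples


def read_maxima_archive(path: str | Path) -> tuple[list[Maximum], dict]:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ArchiveError(f"cannot open maxima archive {path}: {exc}") from exc
    with f:
        for key in ("positions", "values", "counts", "spins"):
            if key not in f:
                raise ArchiveError(f"maxima archive {path} missing dataset {key!r}")
        positions = np.asarray(f["positions"])
        values = np.asarray(f["values"])
        counts = np.asarray(f["counts"])
        spins = np.asarray(f["spins"])
        frozen = (
            np.asarray(f["frozen"])
            if "frozen" in f
            else np.zeros(positions.shape[:2], dtype=bool)
        )
        m = len(positions)
        for name, arr, length in (
            ("values", values, len(values)),
            ("counts", counts, len(counts)),
            ("frozen", frozen, len(frozen)),
        ):
            if length != m:
                raise ArchiveError(
                    f"maxima archive {path} truncated: dataset {name!r} has "
                    f"{length} records, expected {m}"
                )
        if positions.ndim != 3 or positions.shape[1] != len(spins):
            raise ArchiveError(
                f"maxima archive {path}: positions {positions.shape} do not "
                f"match {len(spins)} spins"
            )
        maxima = [
            Maximum(
                configuration=ElectronConfiguration(positions[i], spins.copy()),
                value=float(values[i]),
                count=int(counts[i]),
                frozen=frozen[i],
            )
            for i in range(m)
        ]
        meta = {
            "model": str(f.attrs.get("model", "unknown")),
            "n_total_samples": int(f.attrs.get("n_total_samples", sum(counts))),
        }
    return maxima, meta


# ---------------------------------------------------------------- YAML output
def _listify(array: np.ndarray) -> list:
    return np.asarray(array).tolist()


def cluster_report_dict(
    clusters: list[Cluster],
    geometry: MoleculeGeometry,
    extra: dict | None = None,
) -> dict:
    """Structured cluster report (YAML-serializable, deterministic)."""
    from .motifs import extract_motifs, select_representative, spin_correlation

    out = dict(extra or {})
    out["n_clusters"] = len(clusters)
    rows = []
    for cluster in clusters:
        rep = select_representative(cluster)
        matrix = spin_correlation(cluster)
        partition = extract_motifs(matrix)
        row = {
            "probability": float(cluster.probability),
            "count": int(cluster.count),
            "n_members": cluster.n_members,
            "local": bool(cluster.local),
            "representative": {
                "positions": _listify(rep.positions),
                "spins": _listify(rep.spins),
            },
            "spin_correlation": _listify(np.round(matrix.values, 12)),
            "motifs": [
                {"electrons": motif, "signs": signs, "inconsistent": bool(bad)}
                for motif, signs, bad in zip(
                    partition.motifs, partition.signs, partition.inconsistent
                )
            ],
            "nucleus_electron_counts": nucleus_electron_counts(rep, geometry),
        }
        if cluster.local:
            row["subset_indices"] = [list(map(int, s)) for s in cluster.subset_indices]
        rows.append(row)
    out["clusters"] = rows
    return out


def write_yaml(path: str | Path, data: dict) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_dot_structure(path: str | Path, dot: DotStructure) -> None:
    """Dot-structure YAML: nuclei, electrons with spins, motif edges, P_C."""
    data = {
        "probability": float(dot.probability),
        "nuclei": [
            {"symbol": s, "position": _listify(p)}
            for s, p in zip(dot.geometry.symbols, dot.geometry.positions)
        ],
        "electrons": [
            {"position": _listify(p), "ms": float(ms)}
            for p, ms in zip(dot.positions, dot.spins)
        ],
        "motifs": [list(map(int, m)) for m in dot.motifs],
        "spin_coupled_edges": [[int(i), int(j)] for i, j in dot.motif_edges],
    }
    write_yaml(path, data)


def write_dot_structure_xyz(path: str | Path, dot: DotStructure) -> None:
    """Extended-XYZ export: nuclei plus electrons as pseudo-atoms "X".

    Columns: species, x, y, z, spin (0 for nuclei, +-0.5 for
    electrons); positions in bohr, declared in the comment line.
    """
    lines = []
    n_rows = len(dot.geometry) + len(dot.positions)
    lines.append(str(n_rows))
    lines.append(
        "units=bohr Properties=species:S:1:pos:R:3:spin:R:1 "
        f"probability={dot.probability:.6g}"
    )
    for sym, pos in zip(dot.geometry.symbols, dot.geometry.positions):
        lines.append(f"{sym} {pos[0]:.10f} {pos[1]:.10f} {pos[2]:.10f} 0.0")
    for pos, ms in zip(dot.positions, dot.spins):
        lines.append(f"X {pos[0]:.10f} {pos[1]:.10f} {pos[2]:.10f} {ms:+.1f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_histogram_csv(path: str | Path, hist: np.ndarray, edges: np.ndarray) -> None:
    rows = ["bin_left,bin_right,weight"]
    for left, right, w in zip(edges[:-1], edges[1:], hist):
        rows.append(f"{left:.6f},{right:.6f},{w:.10g}")
    Path(path).write_text("\n".join(rows) + "\n")


# ------------------------------------------------------------- model configs
def load_model_config(spec: str | Path | dict) -> DensityModel:
    """Build a density model from a YAML file or an equivalent dict.

    Recognized ``model`` values: ``h2_cas``, ``h2_rhf``,
    ``slater_determinant``, ``gaussian_mixture``.
    """
    if isinstance(spec, (str, Path)):
        base = Path(spec).parent
        spec = yaml.safe_load(Path(spec).read_text())
    else:
        base = Path(".")
    if not isinstance(spec, dict) or "model" not in spec:
        raise ContractError("model config must be a mapping with a 'model' key")
    name = spec["model"]
    if name == "h2_cas":
        return build_h2_cas(spec.get("r_hh", 1.4), spec.get("zeta", 1.0))
    if name == "h2_rhf":
        return build_h2_hartree_fock(spec.get("r_hh", 1.4), spec.get("zeta", 1.0))
    if name == "slater_determinant":
        geo_spec = spec["geometry"]
        if isinstance(geo_spec, str):
            geometry = read_xyz(base / geo_spec, units=spec.get("units"))
        else:
            geometry = MoleculeGeometry(
                symbols=[a["symbol"] for a in geo_spec],
                positions=np.array([a["position"] for a in geo_spec]),
            )
        orbitals = []
        for orb in spec["orbitals"]:
            prims = []
            for prim in orb:
                center = prim.get("center")
                if isinstance(center, int):
                    center = geometry.positions[center]
                prims.append((np.asarray(center, float), prim["zeta"], prim.get("coeff", 1.0)))
            orbitals.append(STOrbital(primitives=tuple(prims)))
        return SlaterDeterminantDensity(
            geometry=geometry,
            orbitals=orbitals,
            n_alpha=spec["n_alpha"],
            n_beta=spec["n_beta"],
        )
    if name == "gaussian_mixture":
        if "electrons" in spec:
            electrons = [
                (e["weights"], e["centers"], e["sigmas"]) for e in spec["electrons"]
            ]
            return GaussianMixtureDensity(electrons=electrons, spins=spec.get("spins"))
        joint = spec["joint"]
        return GaussianMixtureDensity(
            joint=(joint["weights"], np.asarray(joint["centers"], float), joint["sigmas"]),
            spins=spec.get("spins"),
        )
    raise ContractError(f"unknown model {name!r}")


BUILTIN_MODELS = ("h2_cas", "h2_rhf")


def resolve_model(name_or_path: str) -> DensityModel:
    """CLI helper: a builtin model name or a YAML config path."""
    if name_or_path in BUILTIN_MODELS:
        return load_model_config({"model": name_or_path})
    return load_model_config(name_or_path)
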