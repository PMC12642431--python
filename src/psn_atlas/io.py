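"""Plain-text I/O: TSV/MatrixMarket expression matrices, trace CSVs with
JSON protocol sidecars, YAML configs, and hashed output manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError
from .sim.physio import EMGTrace, FlowTrace


def write_matrix_tsv(matrix: ad.AnnData, path: str | Path) -> None:
    """Write genes x cells TPM as TSV."""
    df = pd.DataFrame(
        np.asarray(matrix.X).T, index=matrix.var_names, columns=matrix.obs_names
    )
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_matrix_tsv(path: str | Path, covariates: str | Path | None = None) -> ad.AnnData:
    """Read a genes x cells TSV (and optional per-cell covariate TSV)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    adata = ad.AnnData(
        X=df.to_numpy().T, obs=pd.DataFrame(index=df.columns), var=pd.DataFrame(index=df.index)
    )
    if covariates is not None:
        cov = pd.read_csv(covariates, sep="\t", index_col=0)
        missing = set(adata.obs_names) - set(cov.index)
        if missing:
            raise InputError(f"covariate table missing cells: {sorted(missing)[:5]} ...")
        adata.obs = cov.loc[adata.obs_names].copy()
    return adata


def write_matrix_mtx(matrix: ad.AnnData, out_dir: str | Path) -> None:
    """Write MatrixMarket (genes x cells) with genes.tsv / cells.tsv sidecars."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), csr_matrix(np.asarray(matrix.X).T))
    pd.Series(matrix.var_names).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.obs_names).to_csv(out / "cells.tsv", sep="\t", index=False, header=False)


def write_trace_csv(trace: FlowTrace | EMGTrace, path: str | Path) -> None:
    """Two-column CSV (time_s, value) plus a JSON sidecar with protocol
    annotations and the simulation truth table."""
    path = Path(path)
    value = trace.flow if isinstance(trace, FlowTrace) else trace.emg
    pd.DataFrame({"time_s": trace.t, "value": value}).to_csv(
        path, index=False, float_format="%.6g"
    )
    sidecar = {"fs": trace.fs, "meta": trace.meta}
    if isinstance(trace, EMGTrace):
        sidecar["hold_windows"] = trace.hold_windows
    sidecar["truth"] = trace.truth.to_dict(orient="list")
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, default=float))


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, float, dict]:
    """Read a 2-column trace CSV; returns (values, fs, sidecar)."""
    df = pd.read_csv(path)
    t, v = df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
    sidecar_path = Path(path).with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    fs = sidecar.get("fs") or (1.0 / np.median(np.diff(t)))
    return v, float(fs), sidecar


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, params: dict) -> Path:
    """Write a manifest listing every artifact with its content hash."""
    out = Path(out_dir)
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "parameters": params,
        "files": {str(p.relative_to(out)): file_sha256(p) for p in files},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return path
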