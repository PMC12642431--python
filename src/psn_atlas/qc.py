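"""Cell-level quality control for full-length single-cell TPM matrices.

Two stages, applied in order:

1. depth filters — cells with fewer than 2 million mapped read pairs or
   fewer than 10,000 expressed endogenous genes are excluded ("expressed"
   meaning TPM >= 1, the single detectability threshold used throughout the
   package);
2. glial-contamination removal — PCA on a satellite-glia gene panel; cells
   whose standardized first-PC score exceeds a cutoff are treated as
   glial-contaminated and removed.

Each removed cell is attributed to the first criterion it fails, in the
order reads -> genes -> glial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = ["QCThresholds", "QCReport", "filter_cells", "glial_score", "remove_glial", "apply_qc"]


@dataclass
class QCThresholds:
    """Cell-level QC thresholds.

    ``min_read_pairs`` and ``min_expressed_genes`` are inclusive lower
    bounds: a cell at exactly the threshold is retained.
    """

    min_read_pairs: int = 2_000_000
    min_expressed_genes: int = 10_000
    glial_panel: list[str] = field(default_factory=list)
    glial_pc_cutoff: float = 2.5

    def validate(self) -> None:
        if self.min_read_pairs <= 0 or self.min_expressed_genes <= 0:
            raise ConfigurationError("QC thresholds must be positive")
        if not np.isfinite(self.glial_pc_cutoff):
            raise ConfigurationError("glial_pc_cutoff must be finite")


@dataclass
class QCReport:
    n_input: int
    n_failed_reads: int = 0
    n_failed_genes: int = 0
    n_glial_removed: int = 0
    verdicts: pd.DataFrame | None = None

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_failed_reads - self.n_failed_genes - self.n_glial_removed

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_failed_reads": self.n_failed_reads,
            "n_failed_genes": self.n_failed_genes,
            "n_glial_removed": self.n_glial_removed,
            "n_retained": self.n_retained,
        }


def filter_cells(
    matrix: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, QCReport]:
    """Apply the read-depth and expressed-gene-count filters.

    Requires per-cell covariates ``mapped_read_pairs`` and
    ``expressed_gene_count`` in ``matrix.obs``. Returns the retained
    submatrix and an exhaustive per-cell verdict table; a cell failing both
    criteria is attributed to the read filter.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    for col in ("mapped_read_pairs", "expressed_gene_count"):
        if col not in matrix.obs:
            raise InputError(f"missing per-cell covariate {col!r}")
    reads = matrix.obs["mapped_read_pairs"].to_numpy(float)
    genes = matrix.obs["expressed_gene_count"].to_numpy(float)
    fail_reads = reads < thresholds.min_read_pairs
    fail_genes = (~fail_reads) & (genes < thresholds.min_expressed_genes)
    keep = ~(fail_reads | fail_genes)
    verdict = np.where(fail_reads, "fail_reads", np.where(fail_genes, "fail_genes", "pass"))
    report = QCReport(
        n_input=matrix.n_obs,
        n_failed_reads=int(fail_reads.sum()),
        n_failed_genes=int(fail_genes.sum()),
        verdicts=pd.DataFrame({"verdict": verdict}, index=matrix.obs_names),
    )
    return matrix[keep].copy(), report


def glial_score(matrix: ad.AnnData, glial_panel: list[str]) -> np.ndarray:
    """Per-cell glial-contamination score.

    Score = coordinate of each cell on the first principal component of the
    glial-panel submatrix in log2(TPM+1), with each gene standardized, and
    the sign fixed so that higher scores mean more glial (positive
    correlation with the panel mean).
    """
    panel = [g for g in glial_panel if g in matrix.var_names]
    if len(panel) < 2:
        raise InputError(
            f"need >=2 glial panel genes present in matrix, found {len(panel)}"
        )
    sub = np.log2(np.asarray(matrix[:, panel].X) + 1.0)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    nz = sd > 0
    if not nz.any():
        return np.zeros(matrix.n_obs)
    z = (sub[:, nz] - mu[nz]) / sd[nz]
    # PC1 via SVD of the centered, standardized panel submatrix
    zc = z - z.mean(axis=0)
    u, s, _ = np.linalg.svd(zc, full_matrices=False)
    score = u[:, 0] * s[0]
    panel_mean = sub.mean(axis=1)
    if np.std(panel_mean) > 0 and np.corrcoef(score, panel_mean)[0, 1] < 0:
        score = -score
    return score


def remove_glial(
    matrix: ad.AnnData, glial_panel: list[str], cutoff: float = 2.5
) -> tuple[ad.AnnData, QCReport]:
    """Remove glial-contaminated cells.

    Cells whose standardized (z-scored across cells) glial PC1 score exceeds
    ``cutoff`` are removed. A cutoff of +inf disables removal; NaN is a
    configuration error.
    """
    if np.isnan(cutoff):
        raise ConfigurationError("glial cutoff must not be NaN")
    score = glial_score(matrix, glial_panel)
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    remove = z > cutoff
    verdict = np.where(remove, "fail_glial", "pass")
    report = QCReport(
        n_input=matrix.n_obs,
        n_glial_removed=int(remove.sum()),
        verdicts=pd.DataFrame(
            {"verdict": verdict, "glial_z": z}, index=matrix.obs_names
        ),
    )
    return matrix[~remove].copy(), report


def apply_qc(
    matrix: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, QCReport]:
    """Full QC: depth filters then glial removal (if a panel is configured).

    The combined report attributes each removed cell to the first criterion
    it failed (reads -> genes -> glial).
    """
    thresholds = thresholds or QCThresholds()
    panel = thresholds.glial_panel or list(matrix.uns.get("glial_panel", []))
    kept, rep1 = filter_cells(matrix, thresholds)
    if panel:
        kept, rep2 = remove_glial(kept, panel, thresholds.glial_pc_cutoff)
        verdicts = rep1.verdicts.copy()
        verdicts.loc[rep2.verdicts.index, "verdict"] = rep2.verdicts["verdict"]
        report = QCReport(
            n_input=rep1.n_input,
            n_failed_reads=rep1.n_failed_reads,
            n_failed_genes=rep1.n_failed_genes,
            n_glial_removed=rep2.n_glial_removed,
            verdicts=verdicts,
        )
    else:
        report = rep1
    return kept, report
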