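"""Merged-platform embedding and paired-cell distances.

Each platform's matrix is log-normalized, reduced to highly variable genes
and z-scored independently; the merged cells-by-genes matrix is then
projected to principal components, and a 2-D embedding (first two PCs by
default; a nonlinear method is pluggable) yields a Euclidean distance
between the two platform points of every common cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from molmatch.quantify import CountMatrix, lognormalize


@dataclass
class PairedEmbedding:
    coords: pd.DataFrame       # index (cell, platform), columns dim1/dim2
    distances: pd.Series       # per common cell
    provenance: dict


def select_hvg(normalized: pd.DataFrame, n: int = 3000) -> list[str]:
    """Top-n genes by residual variance around a mean-variance trend.

    The trend is a running median of log10 variance over quantile bins of
    log10 mean (linearly interpolated), a robust stand-in for a local
    regression that is immune to single-gene leverage; genes are ranked by
    their residual above the trend.
    """
    mean = normalized.mean(axis=1)
    var = normalized.var(axis=1)
    ok = var > 0
    if int(ok.sum()) <= n:
        return sorted(var.index[ok])
    lm = np.log10(mean[ok] + 1e-12).to_numpy()
    lv = np.log10(var[ok]).to_numpy()
    n_bins = min(20, max(2, len(lm) // 20))
    edges = np.quantile(lm, np.linspace(0, 1, n_bins + 1))
    centers, medians = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (lm >= lo) & (lm <= hi)
        if sel.any():
            centers.append(float(np.median(lm[sel])))
            medians.append(float(np.median(lv[sel])))
    trend = np.interp(lm, centers, medians)
    resid = lv - trend
    order = np.argsort(-resid, kind="stable")
    genes = var.index[ok].to_numpy()[order][:n]
    return sorted(genes)


def _scale(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=1)
    sd = df.std(axis=1).replace(0, 1.0)
    return df.sub(mu, axis=0).div(sd, axis=0)


def embed_pairs(matrix_short: CountMatrix, matrix_long: CountMatrix,
                n_hvg: int = 3000, n_pcs: int = 30, method: str = "pca",
                seed: int = 0, scale_factor: float = 1e4) -> PairedEmbedding:
    """Embed both platforms' cells jointly and measure paired distances."""
    norm_s = lognormalize(matrix_short, scale_factor)
    norm_l = lognormalize(matrix_long, scale_factor)
    hvg = sorted(set(select_hvg(norm_s, n_hvg)) | set(select_hvg(norm_l, n_hvg)))
    genes = [g for g in hvg if g in norm_s.index and g in norm_l.index]
    xs = _scale(norm_s.loc[genes])
    xl = _scale(norm_l.loc[genes])
    merged = pd.concat(
        [xs.T.set_index(pd.MultiIndex.from_product([xs.columns, ["short"]])),
         xl.T.set_index(pd.MultiIndex.from_product([xl.columns, ["long"]]))])
    n_pcs = min(n_pcs, merged.shape[0] - 1, merged.shape[1])
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(merged.to_numpy())

    if method == "umap":
        import umap
        coords2 = umap.UMAP(n_components=2, random_state=seed).fit_transform(pcs)
    else:
        coords2 = pcs[:, :2]
    coords = pd.DataFrame(coords2, index=merged.index, columns=["dim1", "dim2"])

    cells_s = set(xs.columns)
    cells_l = set(xl.columns)
    common = sorted(cells_s & cells_l)
    dist = {}
    for c in common:
        p1 = coords.loc[(c, "short")].to_numpy()
        p2 = coords.loc[(c, "long")].to_numpy()
        dist[c] = float(np.hypot(*(p1 - p2)))
    distances = pd.Series(dist).sort_index()
    prov = {"n_hvg": len(genes), "n_pcs": int(n_pcs), "method": method,
            "seed": seed,
            "n_unpaired": len(cells_s ^ cells_l)}
    return PairedEmbedding(coords, distances, prov)
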