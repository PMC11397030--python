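"""Genetic-ancestry classification from principal components.

Target samples are pooled with reference anchor samples of known ancestry
(e.g. 1000 Genomes AFR / EAS / EUR), embedded with PCA on standardised
dosages, and classified two ways:

* :func:`anchored_kmeans` — k-means with centroids initialised at the
  anchor-group means (diagnostic clustering);
* :func:`classify_european` — the authoritative European / non-European
  call: a sample is European iff its PC1 and PC2 both fall within
  [min - 1.96 sd, max + 1.96 sd] of the European anchors' corresponding
  components (closed interval).

Both rules depend only on distances/intervals derived from the anchors,
so they are invariant to the sign indeterminacy of eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypePanel


@dataclass
class PcEmbedding:
    """Principal-component coordinates with optional anchor labels.

    ``frame`` columns: sample, pc1, pc2, ... pcN, anchor (empty string for
    target samples).
    """

    frame: pd.DataFrame
    explained_variance_ratio: np.ndarray | None = None

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("pc")]

    def coords(self, mask=None) -> np.ndarray:
        df = self.frame if mask is None else self.frame[mask]
        return df[self.pc_columns].to_numpy(dtype=float)


@dataclass(frozen=True)
class AncestryCall:
    sample: str
    label: str  # "European" | "non-European"


def pca_embed(
    panel: GenotypePanel,
    n_components: int = 2,
    anchors: dict[str, str] | None = None,
) -> PcEmbedding:
    """PCA on the dosage matrix with the usual genotype standardisation.

    Missing dosages are mean-imputed per variant; each variant column is
    centred at 2p and scaled by sqrt(2p(1-p)); monomorphic variants are
    dropped.  Components are ordered by explained variance.  ``anchors``
    maps sample id to a reference-population label.
    """
    X = panel.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p = col_mean / 2.0
    var = 2 * p * (1 - p)
    poly = var > 0
    if poly.sum() < n_components:
        raise ValueError(
            f"need >= {n_components} polymorphic variants, have {int(poly.sum())}")
    Z = (X[:, poly] - 2 * p[poly]) / np.sqrt(var[poly])
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    coords = U[:, :n_components] * S[:n_components]
    evr = (S**2) / (S**2).sum()

    frame = pd.DataFrame({"sample": panel.samples})
    for i in range(n_components):
        frame[f"pc{i + 1}"] = coords[:, i]
    anchors = anchors or {}
    frame["anchor"] = [anchors.get(s, "") for s in panel.samples]
    return PcEmbedding(frame=frame, explained_variance_ratio=evr[:n_components])


def anchored_kmeans(embedding: PcEmbedding, k: int = 3) -> pd.Series:
    """K-means over the embedding, centroids initialised at anchor means.

    Deterministic: a single Lloyd run (tol 1e-8, max 300 iterations) from
    the anchor-group centroids.  Returns a Series of anchor-group labels
    indexed by sample id.
    """
    from sklearn.cluster import KMeans

    df = embedding.frame
    groups = sorted(g for g in df["anchor"].unique() if g)
    if len(groups) < k:
        raise ValueError(f"k={k} exceeds the {len(groups)} anchor groups present")
    groups = groups[:k]
    centroids = np.vstack([
        embedding.coords(df["anchor"] == g).mean(axis=0) for g in groups
    ])
    km = KMeans(n_clusters=k, init=centroids, n_init=1, max_iter=300, tol=1e-8)
    labels = km.fit_predict(embedding.coords())
    # clusters keep their seed identity: map each final centroid to the
    # nearest initial (anchor) centroid
    order = [int(np.argmin(((c - centroids) ** 2).sum(axis=1))) for c in km.cluster_centers_]
    named = [groups[order[l]] for l in labels]
    return pd.Series(named, index=df["sample"].to_numpy(), name="cluster")


def classify_european(
    embedding: PcEmbedding, eur_label: str = "EUR", sd_factor: float = 1.96
) -> list[AncestryCall]:
    """European / non-European calls by the anchor min-max interval rule.

    For each PC, the European anchors' minimum, maximum and standard
    deviation define the closed acceptance interval
    [min - 1.96 sd, max + 1.96 sd]; a sample is European iff every PC
    falls inside its interval.  Anchor samples are classified too (all
    European anchors necessarily pass their own rule).
    """
    df = embedding.frame
    eur = df["anchor"] == eur_label
    if eur.sum() < 2:
        raise ValueError("need >= 2 European anchor samples to define the rule")
    calls = []
    pcs = embedding.pc_columns
    lo = {}
    hi = {}
    for c in pcs:
        v = df.loc[eur, c]
        sd = v.std(ddof=1)
        lo[c] = v.min() - sd_factor * sd
        hi[c] = v.max() + sd_factor * sd
    for _, row in df.iterrows():
        ok = all(lo[c] <= row[c] <= hi[c] for c in pcs)
        calls.append(AncestryCall(sample=row["sample"],
                                  label="European" if ok else "non-European"))
    return calls
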