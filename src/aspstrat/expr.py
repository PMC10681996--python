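"""Gene-count filtering, normalization, signature scoring and the ASP screen.

Counts enter as a genes x samples DataFrame.  Low-count genes (total count
<= 1 across all samples) are removed, library-size differences are
corrected by median-of-ratios size factors, and per-sample scores are
computed for generic gene signatures (mean z-score of log2(x+1)) and for
the EPPI risk score (a published 29-gene linear model; the package ships a
clearly labelled synthetic example model, see :func:`example_eppi_model`).

The correlation screen asks whether a signature's association with tumor
asphericity reproduces across cohorts: Spearman rank correlation per
cohort, flagged reproducible when the sign agrees in every cohort and the
nominal p is below 0.05 in each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "SignatureDef",
    "EppiModel",
    "filter_genes",
    "size_factors",
    "normalize",
    "signature_score",
    "eppi_score",
    "correlation_screen",
    "example_eppi_model",
    "load_gmt",
    "load_eppi_model",
]

log = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with a processing-stage tag.

    ``stage`` is one of ``raw``, ``filtered``, ``normalized``; operations
    check it so the median-of-ratios factors are always computed on
    filtered counts and scores on normalized values.
    """

    values: pd.DataFrame
    stage: str = "raw"
    cohorts: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("raw", "filtered", "normalized"):
            raise ValueError(f"unknown stage {self.stage!r}")
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (v.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.cohorts is not None and not self.cohorts.index.equals(v.columns):
            self.cohorts = self.cohorts.reindex(v.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class SignatureDef:
    name: str
    abbreviation: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


@dataclass
class EppiModel:
    """Linear risk model: score = intercept + sum coef_g * transform(expr_g)."""

    coefficients: dict[str, float]
    transform: str = "log2p1"
    intercept: float = 0.0
    n_genes_expected: int = 29

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.n_genes_expected:
            raise ValueError(
                f"EPPI model needs {self.n_genes_expected} genes, got {len(self.coefficients)}"
            )
        if not all(np.isfinite(list(self.coefficients.values()))):
            raise ValueError("EPPI coefficients must be finite")
        if self.transform not in ("log2p1", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def apply_transform(self, values: pd.DataFrame) -> pd.DataFrame:
        if self.transform == "log2p1":
            return np.log2(values + 1.0)
        return values


def example_eppi_model(seed: int = 2029) -> EppiModel:
    """SYNTHETIC stand-in for the published 29-gene EPPI model.

    The real coefficients are external input; this deterministic example
    (placeholder gene symbols EPPIG01..EPPIG29, coefficients drawn once
    from a fixed-seed normal) exists so the scoring pipeline is fully
    exercisable without them.  It is not the published model.
    """
    rng = np.random.default_rng(seed)
    genes = [f"EPPIG{i:02d}" for i in range(1, 30)]
    coefs = rng.normal(0.0, 0.3, size=29)
    coefs[::2] = np.abs(coefs[::2])  # mix of risk and protective genes
    coefs[1::2] = -np.abs(coefs[1::2])
    return EppiModel(dict(zip(genes, np.round(coefs, 4))))


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------


def filter_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with insufficient counts (total count <= 1 over all samples)."""
    if m.stage != "raw":
        raise ValueError(f"filter_genes expects raw counts, got stage {m.stage!r}")
    totals = m.values.sum(axis=1)
    keep = totals > 1
    if not keep.any():
        raise ValueError("no gene passes the total-count > 1 filter")
    removed = int((~keep).sum())
    if removed:
        log.info("filtered %d / %d genes with total count <= 1", removed, len(keep))
    return ExpressionMatrix(m.values.loc[keep], stage="filtered", cohorts=m.cohorts)


def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each gene with all-positive counts the geometric mean across
    samples is the reference; a sample's factor is the median over those
    genes of count / reference.  The median is taken on the log scale
    (DESeq2's convention, which differs from the linear-ratio median only
    in the interpolation at an even gene count).
    """
    if m.stage != "filtered":
        raise ValueError(f"size_factors expects filtered counts, got stage {m.stage!r}")
    counts = m.values.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has all-positive counts; consider a pseudocount before normalization"
        )
    logc = np.log(counts[allpos])
    ref = logc.mean(axis=1, keepdims=True)  # log geometric mean per gene
    factors = np.exp(np.median(logc - ref, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=m.samples, name="size_factor")


def normalize(m: ExpressionMatrix, factors: pd.Series | np.ndarray) -> ExpressionMatrix:
    """Divide each sample's counts by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (m.values.shape[1],):
        raise ValueError(
            f"expected one factor per sample ({m.values.shape[1]}), got shape {factors.shape}"
        )
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return ExpressionMatrix(m.values / factors, stage="normalized", cohorts=m.cohorts)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def signature_score(m: ExpressionMatrix, sig: SignatureDef) -> pd.Series:
    """Per-sample mean of per-gene z-scores of log2(normalized + 1).

    Zero-variance genes contribute z = 0.  Missing signature genes are
    logged; scoring fails only when no signature gene is present.
    """
    if m.stage != "normalized":
        raise ValueError("signature_score expects normalized values")
    present = [g for g in sig.genes if g in m.genes]
    missing = [g for g in sig.genes if g not in m.genes]
    if not present:
        raise ValueError(f"no gene of signature {sig.abbreviation!r} in the matrix: {missing}")
    if missing:
        log.warning("signature %s: %d missing genes %s", sig.abbreviation, len(missing), missing)
    x = np.log2(m.values.loc[present] + 1.0)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    z = (x.sub(mu, axis=0)).div(sd.where(sd > 0, np.inf), axis=0)  # zero-variance -> 0
    return z.mean(axis=0).rename(sig.abbreviation)


def eppi_score(
    m: ExpressionMatrix, model: EppiModel, min_gene_fraction: float = 1.0
) -> pd.Series:
    """Linear EPPI risk score per sample.

    In strict mode (default) every model gene must be present; with
    ``min_gene_fraction`` < 1 a warning is emitted for missing genes as
    long as the available fraction suffices.
    """
    if m.stage != "normalized":
        raise ValueError("eppi_score expects normalized values")
    genes = list(model.coefficients)
    present = [g for g in genes if g in m.genes]
    missing = [g for g in genes if g not in m.genes]
    if len(present) < min_gene_fraction * len(genes):
        raise ValueError(f"missing EPPI genes beyond tolerance: {missing}")
    if missing:
        log.warning("EPPI score computed without %d missing genes: %s", len(missing), missing)
    x = model.apply_transform(m.values.loc[present])
    coefs = pd.Series({g: model.coefficients[g] for g in present})
    return (x.mul(coefs, axis=0).sum(axis=0) + model.intercept).rename("EPPI")


# ---------------------------------------------------------------------------
# Signature-ASP correlation screen
# ---------------------------------------------------------------------------


def correlation_screen(
    scores: pd.DataFrame,
    asp: pd.Series,
    cohorts: pd.Series,
    alpha: float = SIGNIFICANCE_LEVEL,
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-signature, per-cohort rank correlation with ASP.

    Returns one row per (signature, cohort) with rho and p, plus a
    ``reproducible`` flag per signature: rho has the same sign in every
    cohort and nominal p < alpha in each.  Cohorts need >= 3 patients
    with both values; a constant score or ASP within a cohort makes rho
    undefined (reported missing, flag False).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    labels = [c for c in pd.unique(cohorts.dropna())]
    for sig in scores.columns:
        per_cohort = []
        for cohort in labels:
            idx = cohorts.index[cohorts == cohort]
            s = scores.loc[scores.index.intersection(idx), sig].dropna()
            a = asp.reindex(s.index).dropna()
            s = s.reindex(a.index)
            if len(s) < 3:
                raise ValueError(f"cohort {cohort!r} has fewer than 3 patients with {sig} and ASP")
            if s.nunique() < 2 or a.nunique() < 2:
                per_cohort.append((cohort, np.nan, np.nan, len(s)))
                continue
            rho, p = corr(s.to_numpy(), a.to_numpy())
            per_cohort.append((cohort, float(rho), float(p), len(s)))
        rhos = [r for _, r, _, _ in per_cohort]
        ps = [p for _, _, p, _ in per_cohort]
        reproducible = (
            all(np.isfinite(r) for r in rhos)
            and len({np.sign(r) for r in rhos}) == 1
            and np.sign(rhos[0]) != 0
            and all(p < alpha for p in ps)
        )
        for cohort, rho, p, n in per_cohort:
            rows.append((sig, cohort, rho, p, n, bool(reproducible)))
    return pd.DataFrame(
        rows, columns=["signature", "cohort", "rho", "p", "n", "reproducible"]
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def load_counts_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV count matrix (gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, stage="raw")


def save_counts_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def load_gmt(path: str | Path) -> list[SignatureDef]:
    """GMT-like signature file: name <tab> description <tab> gene1 <tab> ..."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sigs.append(SignatureDef(parts[0], parts[1] or parts[0], tuple(parts[2:])))
    return sigs


def load_eppi_model(path: str | Path) -> EppiModel:
    """EPPI model CSV (columns gene, coefficient) with an optional YAML
    header in leading ``#`` comment lines (keys: transform, intercept)."""
    import yaml

    header_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            header_lines.append(line.lstrip("# "))
        else:
            break
    meta = yaml.safe_load("\n".join(header_lines)) or {} if header_lines else {}
    df = pd.read_csv(path, comment="#")
    coefs = dict(zip(df["gene"], df["coefficient"].astype(float)))
    return EppiModel(
        coefs,
        transform=meta.get("transform", "log2p1"),
        intercept=float(meta.get("intercept", 0.0)),
        n_genes_expected=len(coefs),
    )
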