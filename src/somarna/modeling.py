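"""Penalized Poisson models of the genewise mutation rate, plus recurrence,
entropy and mutational-signature summaries.

The central model treats the mutation count m_n of one (gene, strand
class) row as Poisson with

    E[m_n] / b_n = exp( alpha + kappa * log(d*_n) + gamma * 1[template]
                        + X_n . beta )

where b_n (effective gene length) enters as an offset, d*_n is the
normalized transcriptional depth, and X_n the standardized genomic
covariates.  kappa, gamma and beta carry an L1 (LASSO) penalty whose
weight is tuned by K-fold cross-validation on held-out Poisson deviance;
the intercept alpha is never penalized.

The solver is the standard penalized-IRLS coordinate descent: an outer
iteratively-reweighted least-squares loop with cyclic soft-threshold
updates on the weighted working response, warm-started along a descending
log-spaced penalty path from lambda_max (the smallest penalty that zeroes
every penalized coefficient).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import NMF

from somarna.annotation import COMPLEMENT

logger = logging.getLogger(__name__)

_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# Poisson LASSO


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Per-observation Poisson deviance 2[y log(y/mu) - (y - mu)]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * (term - (y - mu))


def _irls_lasso(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    lam: float,
    coef: np.ndarray,
    intercept: float,
    max_irls: int = 15,
    max_cd: int = 40,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """One L1-penalized Poisson fit at penalty ``lam`` (warm-started).

    Outer IRLS quadratic approximations; inner cyclic coordinate descent
    with soft thresholding, iterating on the active set between full
    sweeps (the glmnet strategy).
    """
    n, p = X.shape

    def _cd_pass(w, resid, wsum, wxx, js, intercept):
        max_delta = 0.0
        new_intercept = intercept + (w @ resid) / wsum
        resid -= new_intercept - intercept
        max_delta = abs(new_intercept - intercept)
        intercept = new_intercept
        for j in js:
            xj = X[:, j]
            if wxx[j] <= 0:
                continue
            rho = w @ (xj * resid) + wxx[j] * coef[j]
            new_b = _soft_threshold(rho, n * lam) / wxx[j]
            delta = new_b - coef[j]
            if delta != 0.0:
                resid -= xj * delta
                coef[j] = new_b
                max_delta = max(max_delta, abs(delta))
        return resid, intercept, max_delta

    all_js = range(p)
    for _ in range(max_irls):
        eta = np.clip(offset + intercept + X @ coef, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu
        # working response minus offset; the residual term is clipped to
        # keep near-zero fitted means from destabilizing the updates
        z = (eta - offset) + np.clip((y - mu) / mu, -1e4, 1e4)
        wsum = w.sum()
        wxx = (w[:, None] * X * X).sum(axis=0)
        resid = z - intercept - X @ coef
        old_outer = coef.copy()
        old_intercept = intercept
        for _ in range(8):
            resid, intercept, delta_full = _cd_pass(w, resid, wsum, wxx, all_js, intercept)
            if delta_full < tol:
                break
            active = np.nonzero(coef)[0]
            for _ in range(max_cd):
                resid, intercept, delta_act = _cd_pass(w, resid, wsum, wxx, active, intercept)
                if delta_act < tol:
                    break
        if (
            abs(intercept - old_intercept) < tol
            and np.max(np.abs(coef - old_outer), initial=0.0) < tol
        ):
            break
    return coef, intercept


def lambda_max(X: np.ndarray, y: np.ndarray, offset: np.ndarray) -> float:
    """Smallest penalty zeroing all penalized coefficients (KKT bound)."""
    n = len(y)
    alpha0 = np.log(y.sum() / np.exp(offset).sum())
    mu0 = np.exp(offset + alpha0)
    grad = X.T @ (y - mu0) / n
    return float(np.max(np.abs(grad)))


def poisson_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the penalty path (descending ``lambdas``) with warm starts.

    Returns (coefs of shape [n_lambda, p], intercepts).
    """
    n, p = X.shape
    # center penalized columns for conditioning; the intercept absorbs the
    # shift and is recovered below (coefficients are unaffected)
    col_means = X.mean(axis=0)
    Xc = X - col_means
    coefs = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    coef = np.zeros(p)
    intercept = float(np.log(max(y.sum(), 1e-12) / np.exp(offset).sum()))
    null_dev = poisson_deviance(y, np.exp(offset + intercept)).sum()
    df_max = min(p, max(1, int(0.9 * n)))
    prev_dev = null_dev
    stalls = 0
    for i, lam in enumerate(lambdas):
        coef, intercept = _irls_lasso(Xc, y, offset, lam, coef.copy(), intercept, tol=tol)
        coefs[i] = coef
        intercepts[i] = intercept - col_means @ coef
        # stop the path once the fit saturates or the deviance plateaus
        # (overfit region; later grid points inherit this solution)
        eta = np.clip(offset + intercept + Xc @ coef, -_ETA_CLIP, _ETA_CLIP)
        dev = poisson_deviance(y, np.exp(eta)).sum()
        stalls = stalls + 1 if prev_dev - dev < 1e-5 * null_dev else 0
        prev_dev = dev
        if (
            dev <= 1e-3 * null_dev
            or int((coef != 0).sum()) >= df_max
            or stalls >= 3
        ):
            coefs[i + 1:] = coef
            intercepts[i + 1:] = intercepts[i]
            break
    return coefs, intercepts


def default_lambda_grid(
    lam_max: float, n: int = 100, ratio: float | None = None,
    n_obs: int | None = None, n_features: int | None = None,
) -> np.ndarray:
    """Log-spaced descending penalty grid from lambda_max.

    The grid floor follows the glmnet convention: lambda_max * 1e-4 for
    data-rich problems, raised to lambda_max * 1e-2 when observations are
    scarce relative to predictors (the deep end of the path is then a
    saturated fit with no cross-validation value).
    """
    if ratio is None:
        scarce = (
            n_obs is not None and n_features is not None and n_obs < 5 * n_features
        )
        ratio = 1e-2 if scarce else 1e-4
    return np.geomspace(lam_max, lam_max * ratio, n)


@dataclass
class ModelFit:
    """A fitted penalized Poisson model for one mutation type."""

    mutation_type: str
    alpha: float
    kappa: float
    gamma: float
    beta: pd.Series
    lambda_: float
    cv_path: pd.DataFrame = field(repr=False)
    feature_names: list[str] = field(default_factory=list)

    def coefficients(self) -> pd.Series:
        out = {"(Intercept)": self.alpha, "log_normalized_depth": self.kappa,
               "template_strand": self.gamma}
        out.update(self.beta.to_dict())
        return pd.Series(out)

    def predict_mean(self, X: np.ndarray, log_d: np.ndarray,
                     template: np.ndarray, log_b: np.ndarray) -> np.ndarray:
        eta = (
            log_b + self.alpha + self.kappa * log_d + self.gamma * template
            + X @ self.beta.to_numpy()
        )
        return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


def fit_poisson_lasso(
    table: pd.DataFrame,
    covariate_cols: list[str],
    mutation_type: str = "",
    folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> ModelFit:
    """Cross-validation-tuned LASSO Poisson fit of one modeling table.

    ``table`` must carry columns m, b, d_star, strand_class and the
    covariates.  The design is [log d*, 1[template], covariates], all
    penalized; the penalty minimizing mean held-out Poisson deviance over
    ``folds`` folds is chosen, then the model is refit on all rows.
    """
    rows = table.loc[(table["b"] > 0) & (table["d_star"] > 0)].reset_index(drop=True)
    y = rows["m"].to_numpy(dtype=float)
    offset = np.log(rows["b"].to_numpy(dtype=float))
    log_d = np.log(rows["d_star"].to_numpy(dtype=float))
    template = (rows["strand_class"] == "template").to_numpy(dtype=float)
    Xc = rows[covariate_cols].to_numpy(dtype=float)
    if not np.isfinite(Xc).all() or not np.isfinite(log_d).all():
        raise ValueError("non-finite covariates in modeling table")
    X = np.column_stack([log_d, template, Xc])
    names = ["log_normalized_depth", "template_strand"] + list(covariate_cols)

    if y.sum() == 0:
        warnings.warn(
            f"all mutation counts are zero for {mutation_type or 'table'}; "
            "degenerate intercept-only fit"
        )
        beta = pd.Series(0.0, index=covariate_cols)
        return ModelFit(mutation_type, -np.inf, 0.0, 0.0, beta, np.inf,
                        pd.DataFrame(columns=["lambda", "mean_deviance"]), names)

    lam_max = lambda_max(X, y, offset)
    lambdas = (
        np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        if lambda_grid is not None
        else default_lambda_grid(lam_max, n_obs=len(y), n_features=X.shape[1])
    )

    rng = np.random.default_rng(seed)
    n = len(y)
    fold_id = rng.permutation(n) % folds
    dev = np.zeros((folds, len(lambdas)))
    for k in range(folds):
        tr = fold_id != k
        te = ~tr
        coefs, intercepts = poisson_lasso_path(X[tr], y[tr], offset[tr], lambdas)
        for i in range(len(lambdas)):
            eta = np.clip(
                offset[te] + intercepts[i] + X[te] @ coefs[i], -_ETA_CLIP, _ETA_CLIP
            )
            dev[k, i] = poisson_deviance(y[te], np.exp(eta)).mean()
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    cv_path = pd.DataFrame({"lambda": lambdas, "mean_deviance": mean_dev})

    coefs, intercepts = poisson_lasso_path(X, y, offset, lambdas[: best + 1])
    coef, intercept = coefs[best], intercepts[best]
    beta = pd.Series(coef[2:], index=covariate_cols)
    return ModelFit(
        mutation_type=mutation_type,
        alpha=float(intercept),
        kappa=float(coef[0]),
        gamma=float(coef[1]),
        beta=beta,
        lambda_=float(lambdas[best]),
        cv_path=cv_path,
        feature_names=names,
    )


# ---------------------------------------------------------------------------
# Partial correlations


def partial_correlation_tvalues(
    table: pd.DataFrame, covariate_cols: list[str]
) -> pd.DataFrame:
    """Partial correlation of each covariate with m/b given log d*.

    For covariate x, outcome y = m/b and conditioning variable z = log d*,
    the first-order partial correlation is
    r = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)) with
    t = r sqrt(n - 3) / sqrt(1 - r^2).  Covariates collinear with z (or
    with zero variance) are reported as r = 0 / NaN with a warning.
    """
    rows = table.loc[(table["b"] > 0) & (table["d_star"] > 0)]
    n = len(rows)
    if n < 4:
        raise ValueError("partial correlation needs at least 4 rows")
    y = rows["m"].to_numpy(dtype=float) / rows["b"].to_numpy(dtype=float)
    z = np.log(rows["d_star"].to_numpy(dtype=float))
    out = []
    if y.std() == 0 or z.std() == 0:
        for c in covariate_cols:
            out.append({"covariate": c, "partial_r": np.nan, "t": np.nan})
        return pd.DataFrame(out)
    r_yz = np.corrcoef(y, z)[0, 1]
    for c in covariate_cols:
        x = rows[c].to_numpy(dtype=float)
        if x.std() == 0:
            out.append({"covariate": c, "partial_r": np.nan, "t": np.nan})
            continue
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        if 1 - r_xz**2 < 1e-12:
            warnings.warn(f"{c} is collinear with log normalized depth")
            out.append({"covariate": c, "partial_r": 0.0, "t": 0.0})
            continue
        r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        r = float(np.clip(r, -1.0, 1.0))
        if 1 - r**2 < 1e-15:
            t = np.inf * np.sign(r)
        else:
            t = r * np.sqrt(n - 3) / np.sqrt(1 - r**2)
        out.append({"covariate": c, "partial_r": r, "t": float(t)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Locus recurrence


def build_locus_table(
    candidates: pd.DataFrame, pileup: pd.DataFrame
) -> pd.DataFrame:
    """Per-locus recurrence summary: c (covered accessions), d (summed
    depth), m (cross-accession mutation count) and per-alt accession counts.

    Loci are all positions with nonzero coverage in at least one accession;
    mutation counts come from candidate records (one per accession)."""
    cov = pileup.groupby(["chrom", "pos"]).agg(
        c=("accession", "nunique"), d=("coverage", "sum")
    )
    muts = candidates.groupby(["chrom", "pos"]).agg(m=("accession", "nunique"))
    loci = cov.join(muts, how="left").fillna({"m": 0})
    loci["m"] = loci["m"].astype(int)
    return loci.reset_index()


def fit_recurrence_model(loci: pd.DataFrame):
    """Poisson regression of per-locus mutation count on mean depth.

    E[m_l]/c_l = exp(alpha + beta log(d_l / c_l)) with offset log c_l.
    Returns (alpha, beta, expected counts aligned with ``loci``).
    """
    sub = loci.loc[(loci["c"] >= 1) & (loci["d"] > 0)]
    x = np.log(sub["d"].to_numpy(dtype=float) / sub["c"].to_numpy(dtype=float))
    exog = sm.add_constant(x)
    model = sm.GLM(
        sub["m"].to_numpy(dtype=float),
        exog,
        family=sm.families.Poisson(),
        offset=np.log(sub["c"].to_numpy(dtype=float)),
    )
    res = model.fit()
    alpha, beta = float(res.params[0]), float(res.params[1])
    expected = pd.Series(res.mu, index=sub.index).reindex(loci.index)
    return alpha, beta, expected


def alt_allele_entropy(alt_counts: dict[str, int]) -> float:
    """Entropy (nats) of the alternate-allele distribution at one locus.

    ``alt_counts`` maps alternate base to the number of accessions carrying
    it; probabilities are normalized over the accessions the mutation
    appears in, and 0 log 0 is taken as 0.
    """
    total = sum(alt_counts.values())
    if total == 0:
        raise ValueError("entropy undefined for a locus with no mutations")
    p = np.array([v / total for v in alt_counts.values() if v > 0])
    return float(max(0.0, -(p * np.log(p)).sum()))


def locus_entropy_table(candidates: pd.DataFrame) -> pd.DataFrame:
    """Alternate-allele entropy for every locus mutated in >1 accession."""
    rows = []
    for (chrom, pos), sub in candidates.groupby(["chrom", "pos"]):
        if sub["accession"].nunique() < 2:
            continue
        counts = sub.groupby("alt")["accession"].nunique().to_dict()
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "n_accessions": int(sub["accession"].nunique()),
                "n_alts": len(counts),
                "entropy": alt_allele_entropy(counts),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_accessions", "n_alts", "entropy"])


# ---------------------------------------------------------------------------
# Trinucleotide signatures

PYRIMIDINE_TYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
CONTEXT_BASES = ["A", "C", "G", "T"]
CHANNELS = [
    f"{five}[{mut}]{three}"
    for mut in PYRIMIDINE_TYPES
    for five in CONTEXT_BASES
    for three in CONTEXT_BASES
]


def trinucleotide_channel(ref: str, alt: str, five: str, three: str) -> str:
    """96-channel label; purine references are reverse-complemented."""
    if ref in "CT":
        return f"{five}[{ref}>{alt}]{three}"
    return (
        f"{COMPLEMENT[three]}[{COMPLEMENT[ref]}>{COMPLEMENT[alt]}]"
        f"{COMPLEMENT[five]}"
    )


def build_catalog(
    mutations: pd.DataFrame, reference: dict[str, str]
) -> pd.Series:
    """Tabulate mutations into the 96 trinucleotide channels.

    Mutations whose flanking base falls off the chromosome end are skipped
    and logged.
    """
    counts = pd.Series(0, index=CHANNELS, dtype=int)
    skipped = 0
    for _, row in mutations.iterrows():
        seq = reference[row["chrom"]]
        pos = int(row["pos"])
        if pos - 1 < 0 or pos + 1 >= len(seq):
            skipped += 1
            continue
        ch = trinucleotide_channel(
            row["ref"], row["alt"], seq[pos - 1], seq[pos + 1]
        )
        counts[ch] += 1
    if skipped:
        logger.info("catalog: skipped %d mutations with flank off chromosome", skipped)
    return counts


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


@dataclass
class SignatureDecomposition:
    signatures: pd.DataFrame   # k x 96, rows sum to 1
    exposures: np.ndarray      # n_samples x k
    reconstruction_cosine: float


def extract_signatures(
    catalogs: pd.DataFrame | pd.Series, k: int = 2, seed: int = 0,
    max_iter: int = 2000,
) -> SignatureDecomposition:
    """Deterministic KL non-negative factorization of mutation catalogs.

    ``catalogs`` is an (n_samples x 96) count matrix (a single catalog
    Series is treated as one sample).  Multiplicative-update NMF with the
    Kullback-Leibler objective and a seeded random initialization yields k
    signature probability vectors, per-sample exposures, and the cosine
    similarity between the aggregate catalog and its reconstruction.
    """
    if isinstance(catalogs, pd.Series):
        catalogs = catalogs.to_frame().T
    V = catalogs.to_numpy(dtype=float)
    if k < 1 or k > V.shape[1]:
        raise ValueError(f"k must be in [1, {V.shape[1]}]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = NMF(
            n_components=k,
            solver="mu",
            beta_loss="kullback-leibler",
            init="random",
            random_state=seed,
            max_iter=max_iter,
            tol=1e-10,
        )
        W = model.fit_transform(V)
    H = model.components_
    row_sums = H.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    signatures = pd.DataFrame(H / row_sums, columns=catalogs.columns)
    exposures = W * row_sums.T
    recon = exposures @ signatures.to_numpy()
    cos = cosine_similarity(V.sum(axis=0), recon.sum(axis=0))
    return SignatureDecomposition(signatures, exposures, cos)


def match_signatures(
    found: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Best-match cosine similarity of each found signature to a reference set."""
    rows = []
    for i in range(len(found)):
        sims = [
            cosine_similarity(found.iloc[i].to_numpy(), reference.iloc[j].to_numpy())
            for j in range(len(reference))
        ]
        j = int(np.argmax(sims))
        rows.append({
            "signature": i,
            "best_match": reference.index[j],
            "cosine": sims[j],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-dataset comparison


def compare_effect_sizes(
    fits_a: dict[str, ModelFit], fits_b: dict[str, ModelFit]
) -> tuple[float, float]:
    """Pearson r and Spearman rho over pooled, name-aligned coefficients.

    Coefficients are paired by (mutation type, covariate name) across the
    two fit collections; intercepts are excluded.
    """
    xs, ys = [], []
    for mut_type, fa in fits_a.items():
        fb = fits_b.get(mut_type)
        if fb is None:
            continue
        ca = fa.coefficients().drop("(Intercept)")
        cb = fb.coefficients().drop("(Intercept)")
        shared = ca.index.intersection(cb.index)
        xs.extend(ca[shared].tolist())
        ys.extend(cb[shared].tolist())
    if len(xs) < 3:
        raise ValueError("need at least 3 shared coefficients to compare")
    r = float(stats.pearsonr(xs, ys).statistic)
    rho = float(stats.spearmanr(xs, ys).statistic)
    return r, rho
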