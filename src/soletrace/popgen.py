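"""SNP genotype handling, Weir-Cockerham F_ST and DAPC.

The differentiation statistic is the Weir & Cockerham (1984) variance-
components estimator theta. For a biallelic locus observed in r subpopulations
with sample sizes n_i, alternate-allele frequencies p_i and observed
heterozygote proportions h_i, the among-population (a), among-individual (b)
and within-individual (c) components are

    n_bar = mean(n_i),  n_c = (sum n_i - sum n_i^2 / sum n_i) / (r - 1)
    p_bar = sum n_i p_i / sum n_i
    s2    = sum n_i (p_i - p_bar)^2 / ((r - 1) n_bar)
    h_bar = sum n_i h_i / sum n_i

    a = (n_bar / n_c) * (s2 - (p_bar q_bar - s2 (r-1)/r - h_bar/4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar q_bar - s2 (r-1)/r - h_bar (2 n_bar - 1)/(4 n_bar))
    c = h_bar / 2

with q_bar = 1 - p_bar. The multilocus estimate is the ratio of sums
theta = sum_l a_l / sum_l (a_l + b_l + c_l) (never the mean of per-locus
ratios). Confidence intervals are percentile bootstrap over loci. Negative
estimates are reported as computed.

DAPC (discriminant analysis of principal components) reduces the centered,
mean-imputed genotype matrix by PCA and runs a linear discriminant analysis of
the subunit labels on the retained PC scores; membership probabilities are the
LDA Gaussian posteriors. The retained PC count is chosen by stratified
holdout cross-validation (default 90/10) over a grid of candidate counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = [
    "GenotypeMatrix",
    "FstResult",
    "DapcResult",
    "qc_filter",
    "hwe_exact_test",
    "wc_fst",
    "bootstrap_fst_ci",
    "dapc_fit",
    "dapc_xval",
]


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele counts (0/1/2, NaN = missing)."""

    genotypes: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    subunits: np.ndarray
    years: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.subunits = np.asarray(self.subunits)
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n or len(self.subunits) != n:
            raise ValueError("sample ids / subunit labels must match genotype rows")
        if len(self.locus_ids) != m:
            raise ValueError("locus ids must match genotype columns")
        valid = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotypes must be 0, 1, 2 or missing (NaN)")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def subunit_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.subunits:
            if s not in seen:
                seen.append(str(s))
        return seen

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes[:, mask],
            sample_ids=self.sample_ids,
            locus_ids=[l for l, keep in zip(self.locus_ids, mask) if keep],
            subunits=self.subunits,
            years=self.years,
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes[mask],
            sample_ids=[s for s, keep in zip(self.sample_ids, mask) if keep],
            locus_ids=self.locus_ids,
            subunits=self.subunits[mask],
            years=None if self.years is None else self.years[mask],
        )

    def imputed(self) -> np.ndarray:
        """Genotypes with per-locus mean imputation of missing calls."""
        g = self.genotypes.copy()
        if np.isnan(g).any():
            means = np.nanmean(g, axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            idx = np.where(np.isnan(g))
            g[idx] = means[idx[1]]
        return g


@dataclass
class FstResult:
    """Global and pairwise Weir-Cockerham theta with percentile bootstrap CIs."""

    global_theta: float
    pairwise: pd.DataFrame  # columns: pop1, pop2, theta, lower, upper, significant
    global_ci: tuple[float, float] | None = None
    global_significant: bool | None = None
    n_boot: int = 0
    seed: int | None = None

    def pairwise_matrix(self) -> pd.DataFrame:
        pops = sorted(set(self.pairwise["pop1"]) | set(self.pairwise["pop2"]))
        mat = pd.DataFrame(np.nan, index=pops, columns=pops)
        for row in self.pairwise.itertuples(index=False):
            mat.loc[row.pop1, row.pop2] = row.theta
            mat.loc[row.pop2, row.pop1] = row.theta
        return mat


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic locus.

    Sums the probabilities of all heterozygote configurations (conditional on
    allele counts) no more probable than the observed one.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if n_rare == 0:
        return 1.0
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # log-probability of each heterozygote count given allele counts
    from scipy.special import gammaln

    n_common = 2 * n - n_rare
    het = het_values
    rare_hom = (n_rare - het) // 2
    common_hom = n - het - rare_hom
    logp = (
        het * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(het + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
        + gammaln(n_rare + 1)
        + gammaln(n_common + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[het_values == n_ab][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.1,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop loci failing MAF, missingness or HWE exact-test thresholds.

    A simple configurable stand-in for a full SNP-calling filter cascade.
    Returns the filtered matrix and per-filter drop counts.
    """
    geno = g.genotypes
    n_missing = np.isnan(geno).sum(axis=0)
    miss_frac = n_missing / g.n_samples
    with np.errstate(invalid="ignore"):
        p = np.nanmean(geno, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    fail_missing = miss_frac > max_missing
    fail_maf = maf < maf_min
    fail_hwe = np.zeros(g.n_loci, dtype=bool)
    if hwe_alpha > 0:
        for j in range(g.n_loci):
            col = geno[:, j]
            col = col[~np.isnan(col)]
            n_bb = int((col == 2).sum())
            n_ab = int((col == 1).sum())
            n_aa = int((col == 0).sum())
            fail_hwe[j] = hwe_exact_test(n_aa, n_ab, n_bb) < hwe_alpha
    keep = ~(fail_missing | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("QC removed every locus")
    counts = {
        "input": g.n_loci,
        "fail_missing": int(fail_missing.sum()),
        "fail_maf": int(fail_maf.sum()),
        "fail_hwe": int(fail_hwe.sum()),
        "retained": int(keep.sum()),
    }
    return g.subset_loci(keep), counts


def _wc_components(
    geno: np.ndarray, subunits: np.ndarray, pops: list[str]
) -> np.ndarray:
    """Per-locus W&C (a, b, c) variance components; shape (n_loci, 3).

    Missing genotypes are excluded locus-wise. Loci observed in fewer than two
    subpopulations, or with n_bar <= 1, contribute zeros.
    """
    n_loci = geno.shape[1]
    n_i = np.zeros((len(pops), n_loci))
    p_i = np.zeros((len(pops), n_loci))
    h_i = np.zeros((len(pops), n_loci))
    for i, pop in enumerate(pops):
        block = geno[subunits == pop]
        called = ~np.isnan(block)
        n_i[i] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_i[i] = np.nansum(block, axis=0) / (2.0 * np.maximum(n_i[i], 1))
            h_i[i] = (block == 1).sum(axis=0) / np.maximum(n_i[i], 1)
    present = n_i > 0
    r = present.sum(axis=0).astype(float)
    n_sum = n_i.sum(axis=0)
    ok = (r >= 2) & (n_sum > r)  # need variation in sampling to define n_c
    n_bar = n_sum / np.maximum(r, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (n_sum - (n_i**2).sum(axis=0) / n_sum) / np.maximum(r - 1, 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / (np.maximum(r - 1, 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_sum
        q = p_bar * (1.0 - p_bar)
        inner = q - s2 * (r - 1.0) / r - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            q - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
    comp = np.column_stack([a, b, c])
    bad = ~ok | (n_bar <= 1) | (n_c <= 0) | ~np.isfinite(comp).all(axis=1)
    comp[bad] = 0.0
    return comp


def _theta_from_components(comp: np.ndarray) -> float:
    num = comp[:, 0].sum()
    den = comp.sum()
    if den == 0:
        return float("nan")
    return float(num / den)


def wc_fst(g: GenotypeMatrix) -> FstResult:
    """Multilocus Weir-Cockerham theta: global and for every subunit pair."""
    pops = g.subunit_names()
    if len(pops) < 2:
        raise ValueError("need at least 2 subunits for differentiation")
    for pop in pops:
        block = g.genotypes[g.subunits == pop]
        if (~np.isnan(block)).sum(axis=0).max(initial=0) < 2:
            raise ValueError(f"subunit {pop} has < 2 genotyped individuals at every locus")
    comp = _wc_components(g.genotypes, g.subunits, pops)
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pair = [pops[i], pops[j]]
            mask = np.isin(g.subunits, pair)
            comp_pair = _wc_components(g.genotypes[mask], g.subunits[mask], pair)
            rows.append(
                {
                    "pop1": pops[i],
                    "pop2": pops[j],
                    "theta": _theta_from_components(comp_pair),
                    "lower": np.nan,
                    "upper": np.nan,
                    "significant": None,
                }
            )
    return FstResult(
        global_theta=_theta_from_components(comp),
        pairwise=pd.DataFrame(rows),
    )


def bootstrap_fst_ci(
    g: GenotypeMatrix, n_boot: int = 1000, seed: int | None = None
) -> FstResult:
    """Percentile bootstrap (over loci) 95% CIs for global and pairwise theta.

    A value is flagged significant when its CI excludes zero.
    """
    import warnings

    if g.n_loci < 20:
        warnings.warn("fewer than 20 loci: bootstrap CI will be unstable", stacklevel=2)
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives coarse CI bounds", stacklevel=2)
    rng = np.random.default_rng(seed)
    pops = g.subunit_names()
    result = wc_fst(g)
    idx = rng.integers(0, g.n_loci, size=(n_boot, g.n_loci))

    def _ci(comp: np.ndarray) -> tuple[float, float]:
        a = comp[:, 0]
        abc = comp.sum(axis=1)
        num = a[idx].sum(axis=1)
        den = abc[idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            thetas = num / den
        thetas = thetas[np.isfinite(thetas)]
        lo, hi = np.percentile(thetas, [2.5, 97.5])
        return float(lo), float(hi)

    comp_global = _wc_components(g.genotypes, g.subunits, pops)
    glo = _ci(comp_global)
    result.global_ci = glo
    result.global_significant = bool(glo[0] > 0.0 or glo[1] < 0.0)
    lowers, uppers, sig = [], [], []
    for row in result.pairwise.itertuples(index=False):
        pair = [row.pop1, row.pop2]
        mask = np.isin(g.subunits, pair)
        comp_pair = _wc_components(g.genotypes[mask], g.subunits[mask], pair)
        lo, hi = _ci(comp_pair)
        lowers.append(lo)
        uppers.append(hi)
        sig.append(bool(lo > 0.0 or hi < 0.0))
    result.pairwise["lower"] = lowers
    result.pairwise["upper"] = uppers
    result.pairwise["significant"] = sig
    result.n_boot = n_boot
    result.seed = seed
    return result


@dataclass
class DapcResult:
    """Fitted DAPC: retained PCs, discriminant axes and membership posteriors."""

    n_pc: int
    posteriors: pd.DataFrame  # index sample_id, one column per subunit
    assignments: pd.Series
    discriminant_axes: np.ndarray
    xval_table: pd.DataFrame | None = None


def dapc_fit(g: GenotypeMatrix, n_pc: int, n_da: int | None = None) -> DapcResult:
    """PCA reduction of centered genotypes, then LDA of subunit labels."""
    X = g.imputed()
    max_rank = min(g.n_samples - 1, g.n_loci)
    if not 1 <= n_pc <= max_rank:
        raise ValueError(f"n_pc must be in [1, {max_rank}]")
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(X)
    classes = g.subunit_names()
    n_da = n_da or (len(classes) - 1)
    lda = LinearDiscriminantAnalysis(n_components=min(n_da, len(classes) - 1))
    lda.fit(scores, g.subunits)
    proba = lda.predict_proba(scores)
    post = pd.DataFrame(proba, index=g.sample_ids, columns=list(lda.classes_))
    return DapcResult(
        n_pc=n_pc,
        posteriors=post,
        assignments=post.idxmax(axis=1),
        discriminant_axes=lda.scalings_,
    )


def dapc_xval(
    g: GenotypeMatrix,
    max_pc: int = 30,
    n_rep: int = 1000,
    holdout: float = 0.1,
    seed: int | None = None,
    grid_step: int = 5,
) -> tuple[int, pd.DataFrame]:
    """Stratified-holdout cross-validation of the DAPC retained-PC count.

    For each candidate PC count, ``n_rep`` stratified train/holdout splits are
    scored by the fraction of holdout individuals assigned to their sampling
    subunit; returns the arg-max count and the full table (mean and RMSE of
    the per-split assignment rate). The candidate grid is multiples of
    ``grid_step`` up to ``max_pc`` refined by the arg-max neighborhood.
    """
    labels = g.subunits
    _, counts = np.unique(labels, return_counts=True)
    if (counts * holdout).min() < 1:
        raise ValueError("holdout fraction leaves some subunit without test individuals")
    X = g.imputed()
    max_rank = min(g.n_samples - 1, g.n_loci)
    cap = int(min(max_pc, np.floor(max_rank * (1.0 - holdout)) - 1))
    splitter = StratifiedShuffleSplit(
        n_splits=n_rep, test_size=holdout, random_state=None if seed is None else int(seed)
    )
    splits = list(splitter.split(X, labels))

    def _score(n_pc: int) -> tuple[float, float]:
        rates = []
        for train, test in splits:
            pca = PCA(n_components=n_pc, svd_solver="full")
            s_train = pca.fit_transform(X[train])
            s_test = pca.transform(X[test])
            lda = LinearDiscriminantAnalysis()
            lda.fit(s_train, labels[train])
            rates.append(float(np.mean(lda.predict(s_test) == labels[test])))
        rates = np.asarray(rates)
        return float(rates.mean()), float(np.sqrt(np.mean((1.0 - rates) ** 2)))

    grid = sorted(set(list(range(grid_step, cap + 1, grid_step)) + [cap]))
    grid = [n for n in grid if n >= 1] or [1]
    table: dict[int, tuple[float, float]] = {n: _score(n) for n in grid}
    best = max(table, key=lambda n: table[n][0])
    for n in (best - 2, best - 1, best + 1, best + 2):
        if 1 <= n <= cap and n not in table:
            table[n] = _score(n)
    best = max(sorted(table), key=lambda n: table[n][0])
    df = pd.DataFrame(
        [(n, m, r) for n, (m, r) in sorted(table.items())],
        columns=["n_pc", "mean_assignment", "rmse"],
    )
    return best, df
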