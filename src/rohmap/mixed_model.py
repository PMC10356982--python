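"""GBLUP-style mixed-model validation of candidate ROH regions.

The model is the animal model y = Xb + u + e with u ~ N(0, G sigma_g^2) and
e ~ N(0, I sigma_e^2), where G is the VanRaden (method 1) genomic
relationship matrix built from observed allele frequencies. Each candidate
region enters a separate fit as a binary fixed effect (ROH presence /
absence) alongside the intercept, on all phenotyped genotyped animals.

REML estimation profiles the variance ratio gamma = sigma_g^2 / sigma_e^2:
G (regularized as G + 0.01 I) is eigendecomposed once, the model is rotated
to the eigenbasis where the covariance is diagonal, and the restricted
log-likelihood — profiled analytically over sigma_e^2 — is maximized over
gamma on a log-spaced grid refined by golden-section search. Standard
errors of the fixed effects come from the inverse weighted normal equations
times the residual variance, which coincides with the fixed-effect block of
the inverse mixed-model-equation coefficient matrix.
"""

from __future__ import annotations

import math

import numpy as np

from .types import (
    MISSING,
    GRM,
    GenotypeDataset,
    MixedModelFit,
    OverlapRegion,
    PhenotypeTable,
    PipelineError,
    RegionValidation,
    ROHResult,
    ValidationReport,
)

__all__ = ["compute_grm", "fit_lmm", "validate_regions", "SpectralLMM"]

#: Ridge added to G before inversion/factorization.
GRM_RIDGE: float = 0.01


def compute_grm(dataset: GenotypeDataset) -> GRM:
    """VanRaden method-1 genomic relationship matrix.

    Genotype codes are centered by twice the observed alternate-allele
    frequency p_j; missing codes are imputed to 2 p_j (i.e. contribute
    zero after centering); G = W W' / (2 sum_j p_j (1 - p_j)), with
    monomorphic markers excluded from the denominator (their centered
    column is identically zero).
    """
    if dataset.n_animals < 2:
        raise PipelineError("GRM needs at least 2 animals")
    codes = dataset.genotypes.astype(float)
    missing = dataset.genotypes == MISSING
    codes[missing] = np.nan
    p = np.nanmean(codes, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)  # all-missing marker: no contribution
    w = codes - 2.0 * p
    w[np.isnan(w)] = 0.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise PipelineError("all markers are monomorphic; GRM undefined")
    return GRM(list(dataset.animal_ids), (w @ w.T) / denom)


class SpectralLMM:
    """Reusable REML machinery for one GRM and many (y, X) pairs.

    Eigendecomposes G + ridge*I once; each fit is then a 1-D optimization
    over the variance ratio with closed-form GLS updates in the eigenbasis.
    """

    def __init__(self, grm: GRM | np.ndarray, ridge: float = GRM_RIDGE):
        g = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
        g = g + ridge * np.eye(g.shape[0])
        self.eigvals, self.eigvecs = np.linalg.eigh(g)
        self.n = g.shape[0]

    def fit(
        self,
        y: np.ndarray,
        X: np.ndarray,
        var_ratio: float | None = None,
    ) -> MixedModelFit:
        """REML fit; ``var_ratio`` fixes gamma = sigma_g^2/sigma_e^2 if given.

        ``var_ratio=0.0`` forces sigma_g^2 = 0, which reduces to ordinary
        least squares.
        """
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.n or len(y) != self.n:
            raise PipelineError("y/X dimensions do not match the GRM")
        p = X.shape[1]
        if np.linalg.matrix_rank(X) < p:
            raise PipelineError("fixed-effect design is rank deficient")
        yt = self.eigvecs.T @ y
        xt = self.eigvecs.T @ X

        def profile(gamma: float):
            wts = 1.0 / (gamma * self.eigvals + 1.0)
            xtw = xt * wts[:, None]
            xwx = xt.T @ xtw
            xwy = xtw.T @ yt
            try:
                cho = np.linalg.cholesky(xwx)
            except np.linalg.LinAlgError:
                return -np.inf, None
            beta = np.linalg.solve(xwx, xwy)
            r = yt - xt @ beta
            rss = float(r @ (wts * r))
            df = self.n - p
            if rss <= 0:
                return -np.inf, None
            sigma_e2 = rss / df
            logdet_v = float(np.sum(np.log(gamma * self.eigvals + 1.0)))
            logdet_xwx = 2.0 * float(np.sum(np.log(np.diag(cho))))
            ll = -0.5 * (df * math.log(sigma_e2) + logdet_v + logdet_xwx + df)
            return ll, (beta, xwx, sigma_e2)

        if var_ratio is not None:
            best_gamma = float(var_ratio)
            ll, payload = profile(best_gamma)
            converged = np.isfinite(ll)
        else:
            grid = np.concatenate(([0.0], np.logspace(-4, 4, 65)))
            lls = np.array([profile(g)[0] for g in grid])
            if not np.isfinite(lls).any():
                raise PipelineError(
                    "restricted likelihood non-finite across the variance grid"
                )
            k = int(np.argmax(lls))
            best_gamma = float(grid[k])
            if 0 < k < len(grid) - 1 and grid[k - 1] > 0:
                # golden-section refinement on log(gamma)
                lo, hi = math.log(grid[k - 1]), math.log(grid[k + 1])
                phi = (math.sqrt(5.0) - 1.0) / 2.0
                c = hi - phi * (hi - lo)
                d = lo + phi * (hi - lo)
                fc, fd = profile(math.exp(c))[0], profile(math.exp(d))[0]
                for _ in range(40):
                    if fc >= fd:
                        hi, d, fd = d, c, fc
                        c = hi - phi * (hi - lo)
                        fc = profile(math.exp(c))[0]
                    else:
                        lo, c, fc = c, d, fd
                        d = lo + phi * (hi - lo)
                        fd = profile(math.exp(d))[0]
                refined = math.exp((lo + hi) / 2.0)
                if profile(refined)[0] >= lls[k]:
                    best_gamma = refined
            ll, payload = profile(best_gamma)
            converged = np.isfinite(ll)
        if payload is None:
            raise PipelineError("REML fit failed at the selected variance ratio")
        beta, xwx, sigma_e2 = payload
        cov_beta = np.linalg.inv(xwx) * sigma_e2
        se = np.sqrt(np.diag(cov_beta))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_values = np.where(se > 0, beta / se, 0.0)
        return MixedModelFit(
            beta=beta,
            se=se,
            t_values=t_values,
            sigma_g2=best_gamma * sigma_e2,
            sigma_e2=sigma_e2,
            log_likelihood=float(ll),
            converged=bool(converged),
        )


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    grm: GRM | np.ndarray,
    var_ratio: float | None = None,
) -> MixedModelFit:
    """One-shot REML fit of the animal model (see :class:`SpectralLMM`)."""
    return SpectralLMM(grm).fit(y, X, var_ratio=var_ratio)


def validate_regions(
    regions: list[OverlapRegion],
    dataset: GenotypeDataset,
    result: ROHResult,
    phenotypes: PhenotypeTable,
    threshold: float = 2.0,
) -> ValidationReport:
    """Mixed-model validation of candidate regions on the full population.

    For each region a separate animal model is fitted on all phenotyped
    genotyped animals with fixed effects (intercept, carrier indicator),
    where an animal is a carrier when one of its ROH segments fully covers
    the region. Regions whose indicator is constant are reported as
    untestable rather than raising.
    """
    if not regions:
        raise PipelineError("no regions supplied for validation")
    animals = [a for a in dataset.animal_ids if a in phenotypes.by_animal]
    if len(animals) < 3:
        raise PipelineError("need >= 3 phenotyped genotyped animals")
    grm = compute_grm(dataset).subset(animals)
    lmm = SpectralLMM(grm)
    y = np.array([phenotypes.by_animal[a][0] for a in animals])
    ones = np.ones(len(animals))
    out: list[RegionValidation] = []
    for region in regions:
        x = np.array(
            [
                float(
                    any(
                        seg.covers(region.chromosome, region.start_bp, region.end_bp)
                        for seg in result.per_animal.get(a, [])
                    )
                )
                for a in animals
            ]
        )
        n_carriers = int(x.sum())
        if n_carriers == 0 or n_carriers == len(animals):
            out.append(
                RegionValidation(
                    region, n_carriers, math.nan, math.nan, math.nan,
                    validated=False, untestable=True,
                )
            )
            continue
        fit = lmm.fit(y, np.column_stack([ones, x]))
        t = float(fit.t_values[1])
        out.append(
            RegionValidation(
                region,
                n_carriers,
                float(fit.beta[1]),
                float(fit.se[1]),
                t,
                validated=abs(t) >= threshold,
            )
        )
    return ValidationReport(out, threshold=threshold)
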