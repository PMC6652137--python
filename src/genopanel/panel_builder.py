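"""Build a compressed reference panel from a multi-accession genotype table.

Pipeline: alternate-allele dosage encoding -> minor-allele-frequency
filter -> per-site mean imputation and centering -> deterministic
full-SVD PCA with accessions as observations and sites as features.
The fitted projection (site index, site means, component loadings) is
frozen into a :class:`PanelModel`; the accession score matrix plus the
model form a :class:`ReferencePanel` that queries are placed into.

Conventions fixed here and relied on everywhere else:

* dosage values are alternate-allele counts in ``{0, 1, 2}``, with
  :data:`MISSING` (``-1``) marking no-calls;
* sites with defined MAF strictly below the threshold are removed, as are
  sites with call rate below a configurable floor (default 50%);
* features are mean-centered but not variance-scaled;
* component signs are fixed so the largest-magnitude loading of each
  component is positive (ties broken by lowest site index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyPanelError, ParameterError

#: Sentinel for a missing (no-call) dosage in integer genotype matrices.
MISSING: int = -1

#: Shipped default minor-allele-frequency threshold.
DEFAULT_MAF: float = 0.2

#: Shipped default number of principal components.
DEFAULT_COMPONENTS: int = 20

#: Shipped default minimum per-site call rate.
DEFAULT_CALL_RATE_FLOOR: float = 0.5


@dataclass(frozen=True, order=True)
class SiteKey:
    """One biallelic SNP position; the unit of matching between panel and query.

    ``chrom`` must already be in canonical normalized form (see
    :mod:`genopanel.chromnames`); ``pos`` is 1-based per VCF convention.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParameterError(f"site position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ParameterError(
                f"ref and alt alleles must differ at {self.chrom}:{self.pos}"
            )
        if "," in self.alt or not self.alt:
            raise ParameterError(
                f"panel sites are biallelic; bad alt {self.alt!r} at "
                f"{self.chrom}:{self.pos}"
            )


@dataclass
class GenotypeTable:
    """Sites x accessions alternate-allele dosage matrix with labels.

    ``dosages`` has shape ``(len(sites), len(accessions))`` and dtype
    ``int8`` with entries in ``{0, 1, 2, MISSING}``. ``groups`` optionally
    tags accessions (e.g. wild / cultivar / breeding line).
    """

    sites: list[SiteKey]
    accessions: list[str]
    dosages: np.ndarray
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sites), len(self.accessions)):
            raise ParameterError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"({len(self.sites)} sites, {len(self.accessions)} accessions)"
            )
        if len(set(self.accessions)) != len(self.accessions):
            raise ParameterError("accession labels must be unique")
        bad = (self.dosages > 2) | (self.dosages < MISSING)
        if bad.any():
            raise ParameterError("dosages must be in {0, 1, 2} or MISSING (-1)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def group_of(self, label: str) -> str | None:
        return (self.groups or {}).get(label)


@dataclass
class PanelModel:
    """Frozen projection parameters through which any sample is scored."""

    sites: list[SiteKey]
    site_means: np.ndarray  # (n_sites,) pre-centering mean dosages in [0, 2]
    loadings: np.ndarray  # (n_components, n_sites), rows orthonormal
    evr: np.ndarray  # (n_components,) explained-variance ratios
    maf_threshold: float
    n_components: int

    def __post_init__(self) -> None:
        self.site_means = np.asarray(self.site_means, dtype=np.float64)
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=np.float64))
        self.evr = np.atleast_1d(np.asarray(self.evr, dtype=np.float64))
        n_sites = len(self.sites)
        if self.loadings.shape != (self.n_components, n_sites):
            raise ParameterError(
                f"loadings shape {self.loadings.shape} does not match "
                f"({self.n_components} components, {n_sites} sites)"
            )
        if self.site_means.shape != (n_sites,):
            raise ParameterError("site_means length must equal number of sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def project(self, dosages: np.ndarray) -> np.ndarray:
        """Score one dosage vector (aligned to ``sites``) through the model.

        MISSING entries are imputed with the stored site means, so after
        centering they contribute exactly zero to every component.
        """
        d = np.asarray(dosages)
        if d.shape != (self.n_sites,):
            raise ParameterError(
                f"dosage vector length {d.shape} does not match panel "
                f"({self.n_sites} sites)"
            )
        x = np.where(d == MISSING, self.site_means, d.astype(np.float64))
        return self.loadings @ (x - self.site_means)


@dataclass
class ReferencePanel:
    """PanelModel plus the PC-score matrix of every collection accession."""

    model: PanelModel
    scores: np.ndarray  # (n_components, n_accessions)
    labels: list[str]
    groups: dict[str, str] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=np.float64))
        if self.scores.shape != (self.model.n_components, len(self.labels)):
            raise ParameterError(
                f"score matrix shape {self.scores.shape} does not match "
                f"({self.model.n_components} components, {len(self.labels)} labels)"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("panel accession labels must be unique")

    @property
    def n_accessions(self) -> int:
        return len(self.labels)

    def group_of(self, label: str) -> str | None:
        return (self.groups or {}).get(label)

    def copy(self) -> "ReferencePanel":
        return ReferencePanel(
            model=self.model,
            scores=self.scores.copy(),
            labels=list(self.labels),
            groups=dict(self.groups) if self.groups is not None else None,
            provenance=self.provenance,
        )


def compute_maf(table: GenotypeTable) -> np.ndarray:
    """Per-site minor-allele frequency over non-missing calls.

    For each site ``f = sum(dosages) / (2 * n_called)`` and
    ``MAF = min(f, 1 - f)``, so the result lies in ``[0, 0.5]``. Sites
    with zero non-missing calls get ``nan`` (MAF undefined).
    """
    called = table.dosages != MISSING
    n_called = called.sum(axis=1)
    alt_count = np.where(called, table.dosages, 0).sum(axis=1, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = alt_count / (2.0 * n_called)
    f = np.where(n_called > 0, f, np.nan)
    return np.minimum(f, 1.0 - f)


def call_rate(table: GenotypeTable) -> np.ndarray:
    """Fraction of non-missing calls per site."""
    if table.n_accessions == 0:
        return np.zeros(table.n_sites)
    return (table.dosages != MISSING).sum(axis=1) / table.n_accessions


def filter_by_maf(
    table: GenotypeTable,
    threshold: float = DEFAULT_MAF,
    min_call_rate: float = DEFAULT_CALL_RATE_FLOOR,
) -> GenotypeTable:
    """Retain sites with defined MAF >= ``threshold`` and adequate call rate.

    Site order and the accession set are preserved. Raises
    :class:`EmptyPanelError` if nothing survives: an empty panel is never
    returned silently.
    """
    if not 0.0 < threshold <= 0.5:
        raise ParameterError(
            f"MAF threshold must be in (0, 0.5], got {threshold}"
        )
    if table.n_accessions < 1:
        raise ParameterError("genotype table has no accessions")
    maf = compute_maf(table)
    keep = (~np.isnan(maf)) & (maf >= threshold) & (call_rate(table) >= min_call_rate)
    if not keep.any():
        raise EmptyPanelError(
            f"no site passes MAF >= {threshold} with call rate >= "
            f"{min_call_rate}; cannot build a panel"
        )
    idx = np.flatnonzero(keep)
    return GenotypeTable(
        sites=[table.sites[i] for i in idx],
        accessions=list(table.accessions),
        dosages=table.dosages[idx, :],
        groups=dict(table.groups) if table.groups is not None else None,
    )


def impute_and_center(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing calls, then center each site at zero.

    Returns ``(matrix, site_means)`` where ``matrix`` is float64 with zero
    row means and ``site_means`` are the pre-centering per-site mean
    dosages. Every site must have at least one non-missing call.
    """
    called = table.dosages != MISSING
    n_called = called.sum(axis=1)
    if (n_called == 0).any():
        bad = int(np.flatnonzero(n_called == 0)[0])
        raise ParameterError(
            f"site {table.sites[bad].chrom}:{table.sites[bad].pos} has no "
            "non-missing calls; filter such sites before imputation"
        )
    x = table.dosages.astype(np.float64)
    means = np.where(called, x, 0.0).sum(axis=1) / n_called
    x = np.where(called, x, means[:, None])
    x -= means[:, None]
    return x, means


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip components in place so the max-|loading| entry is positive.

    ``np.argmax`` already resolves ties by lowest index, which pins the
    convention completely.
    """
    for c in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] *= -1.0
            scores[c] *= -1.0


def fit_panel(
    table: GenotypeTable,
    maf_threshold: float = DEFAULT_MAF,
    n_components: int = DEFAULT_COMPONENTS,
    min_call_rate: float = DEFAULT_CALL_RATE_FLOOR,
    provenance: str = "",
) -> ReferencePanel:
    """Filter, encode and PCA-compress a genotype table into a panel.

    Accessions are the observations and sites the features, so a
    collection of N accessions yields an ``n_components x N`` score
    matrix regardless of how many sites survive filtering. The SVD is
    the deterministic full decomposition (no randomized solver).
    """
    filtered = filter_by_maf(table, maf_threshold, min_call_rate)
    bound = min(filtered.n_sites, filtered.n_accessions)
    if not 1 <= n_components <= bound:
        raise ParameterError(
            f"n_components={n_components} must satisfy 1 <= n_components <= "
            f"min(retained sites={filtered.n_sites}, "
            f"accessions={filtered.n_accessions}) = {bound}"
        )
    x, means = impute_and_center(filtered)
    # observations in rows for the SVD: (n_accessions, n_sites)
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    total = float(np.sum(s**2))
    evr_all = (s**2) / total if total > 0 else np.zeros_like(s)
    loadings = vt[:n_components].copy()
    scores = (u[:, :n_components] * s[:n_components]).T.copy()
    _fix_signs(loadings, scores)
    model = PanelModel(
        sites=list(filtered.sites),
        site_means=means,
        loadings=loadings,
        evr=evr_all[:n_components].copy(),
        maf_threshold=maf_threshold,
        n_components=n_components,
    )
    groups = None
    if filtered.groups is not None:
        groups = {a: g for a, g in filtered.groups.items() if a in set(filtered.accessions)}
    return ReferencePanel(
        model=model,
        scores=scores,
        labels=list(filtered.accessions),
        groups=groups,
        provenance=provenance,
    )
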