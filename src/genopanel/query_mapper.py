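"""Align a single-sample, variant-only VCF to a panel and project it.

The central (and easily missed) interpretation rule: variant-only callers
(e.g. ``bcftools call -v``) emit records only where the sample differs
from the reference, so **a panel site with no VCF record is scored as
homozygous reference (dosage 0)** — absence is a call, not missing data.
Without this rule a variant-only VCF is uninterpretable against a fixed
site index. Sites whose record conflicts with the panel alleles (ref
mismatch, or a called alt that is not the panel's alt) and no-calls or
non-diploid GTs are scored MISSING instead, never silently 0, which
protects against queries mapped to the wrong reference genome.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .chromnames import normalize_chrom
from .errors import IncompatibilityError, InputFormatError
from .panel_builder import MISSING, PanelModel

log = logging.getLogger(__name__)

#: Warn when fewer than this fraction of panel sites appear as variant
#: records; deep (>10x) resequencing of a real accession is expected to
#: produce calls at a sizable share of common-allele positions.
DEFAULT_MIN_MATCH_FRACTION = 0.1


@dataclass
class QueryProfile:
    """A query aligned to a panel's site index, with coverage diagnostics.

    The three counters partition the panel site index:
    ``n_matched_variant_records + n_assumed_ref + n_missing == n_sites``.
    """

    label: str
    dosages: np.ndarray  # int8 over panel sites, {0,1,2,MISSING}
    n_matched_variant_records: int
    n_assumed_ref: int
    n_missing: int
    scores: np.ndarray | None = None


def _decode_gt(alleles: list[int], alts: list[str], panel_alt: str) -> int:
    """Dosage of ``panel_alt`` for one diploid GT, or MISSING.

    MISSING for half-calls / no-calls / non-diploid GTs, and for any
    called alt allele that is not the panel's alt (allele conflict).
    """
    if len(alleles) != 2 or any(a < 0 for a in alleles):
        return MISSING
    dosage = 0
    for a in alleles:
        if a == 0:
            continue
        if a - 1 >= len(alts) or alts[a - 1] != panel_alt:
            return MISSING
        dosage += 1
    return dosage


def read_query_vcf(
    path: str,
    model: PanelModel,
    aliases: dict[str, str] | None = None,
    min_match_fraction: float = DEFAULT_MIN_MATCH_FRACTION,
) -> QueryProfile:
    """Convert a single-sample variant-only VCF into a :class:`QueryProfile`.

    Scores are not computed here; see :func:`project_query`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != 1:
        raise InputFormatError(
            f"{path}: query VCFs must contain exactly one sample, found "
            f"{len(samples)} ({samples[:5]}{'...' if len(samples) > 5 else ''}); "
            "split multi-sample files per sample first"
        )
    label = samples[0]

    records: dict[tuple[str, int], list] = {}
    for v in vcf:
        key = (normalize_chrom(v.CHROM, aliases), v.POS)
        records.setdefault(key, []).append(
            (v.REF, list(v.ALT), list(v.genotypes[0][:-1]))
        )

    n_sites = model.n_sites
    dosages = np.empty(n_sites, dtype=np.int8)
    n_matched = n_assumed = n_missing = 0
    n_conflict = 0
    for i, site in enumerate(model.sites):
        recs = records.get((site.chrom, site.pos))
        if recs is None:
            dosages[i] = 0
            n_assumed += 1
            continue
        # prefer the record whose REF matches the panel site
        rec = next((r for r in recs if r[0] == site.ref), None)
        if rec is None:
            dosages[i] = MISSING
            n_missing += 1
            n_conflict += 1
            continue
        ref, alts, alleles = rec
        d = _decode_gt(alleles, alts, site.alt)
        dosages[i] = d
        if d == MISSING:
            n_missing += 1
            if len(alleles) == 2 and all(a >= 0 for a in alleles):
                n_conflict += 1
        else:
            n_matched += 1

    if n_matched == 0 and n_assumed == 0:
        raise InputFormatError(
            f"{path}: zero panel sites matched or assumed homozygous "
            "reference; the query was likely called against a different "
            "reference genome or uses unrecognized chromosome names"
        )
    if n_conflict:
        log.warning(
            "%s: %d panel sites had allele conflicts and were scored missing",
            path, n_conflict,
        )
    if n_matched < min_match_fraction * n_sites:
        log.warning(
            "%s: only %d/%d panel sites appear as variant records (< %.0f%%); "
            "queries are expected to come from >10x resequencing — placement "
            "may be unreliable",
            path, n_matched, n_sites, 100 * min_match_fraction,
        )
    return QueryProfile(
        label=label,
        dosages=dosages,
        n_matched_variant_records=n_matched,
        n_assumed_ref=n_assumed,
        n_missing=n_missing,
    )


def project_query(model: PanelModel, profile: QueryProfile) -> QueryProfile:
    """Score a profile through the pre-trained projection (deterministic).

    MISSING dosages are imputed with the model's site means, the vector is
    centered and multiplied by the component loadings.
    """
    if profile.dosages.shape != (model.n_sites,):
        raise IncompatibilityError(
            f"query profile has {profile.dosages.shape[0]} sites but the "
            f"panel has {model.n_sites}; profile and panel are incompatible"
        )
    return dataclasses.replace(profile, scores=model.project(profile.dosages))
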