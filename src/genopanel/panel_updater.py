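"""Grow an existing panel by projecting new accessions through its frozen model.

New accessions are never used to refit the PCA: their genotypes are
matched to the panel's site index by (chrom, pos, ref, alt), projected
with the same impute-and-center semantics as queries, and appended as
extra score columns. Refitting is a separate, explicit rebuild.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import IncompatibilityError
from .panel_builder import MISSING, GenotypeTable, ReferencePanel

log = logging.getLogger(__name__)


def _dedupe_label(label: str, taken: set[str]) -> str:
    if label not in taken:
        return label
    n = 2
    while f"{label}_{n}" in taken:
        n += 1
    new = f"{label}_{n}"
    log.warning("accession label %r already in panel; renamed to %r", label, new)
    return new


def integrate_accessions(panel: ReferencePanel, table: GenotypeTable) -> ReferencePanel:
    """Return a new panel with ``table``'s accessions appended as score columns.

    Panel sites absent from ``table`` are treated as MISSING for the new
    accessions (site-mean imputation, like queries); table-only sites are
    ignored with a logged count. The model and the pre-existing score
    columns are untouched. Duplicate labels get a ``_2``/``_3`` suffix.
    """
    out = panel.copy()
    if table.n_accessions == 0:
        return out
    model = panel.model
    site_index = {s: i for i, s in enumerate(model.sites)}
    rows = np.full((model.n_sites, table.n_accessions), MISSING, dtype=np.int8)
    n_overlap = 0
    for j, site in enumerate(table.sites):
        i = site_index.get(site)
        if i is not None:
            rows[i, :] = table.dosages[j, :]
            n_overlap += 1
    if n_overlap == 0:
        raise IncompatibilityError(
            "no site of the new genotype table matches the panel's site "
            "index; cannot integrate (check chromosome naming and alleles)"
        )
    if n_overlap < table.n_sites:
        log.info(
            "ignored %d table sites absent from the panel index",
            table.n_sites - n_overlap,
        )

    new_scores = np.column_stack(
        [model.project(rows[:, j]) for j in range(table.n_accessions)]
    )
    taken = set(out.labels)
    new_labels = []
    for label in table.accessions:
        final = _dedupe_label(label, taken)
        taken.add(final)
        new_labels.append(final)

    out.scores = np.hstack([out.scores, new_scores])
    out.labels = out.labels + new_labels
    if table.groups:
        groups = dict(out.groups or {})
        for orig, final in zip(table.accessions, new_labels):
            if orig in table.groups:
                groups[final] = table.groups[orig]
        out.groups = groups
    return out
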