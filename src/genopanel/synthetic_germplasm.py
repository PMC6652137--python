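"""Seeded generator of structured germplasm collections and query VCFs.

Emulates what a real crop collection looks like to the rest of the
package: several diverged populations (Balding–Nichols allele
frequencies around a shared ancestral frequency, divergence set by FST),
pedigree-derived cross offspring, exact-copy redundant accessions, and
randomly masked missing calls. Sites are independent (no linkage
realism); that is enough to exercise filtering, projection, placement
and integration without any external download.

:func:`write_query_vcf` mirrors a variant-only caller: hom-ref sites are
omitted entirely, so readers must apply the absent-site => dosage-0 rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .panel_builder import MISSING, GenotypeTable, SiteKey

_BASES = "ACGT"

#: chromosome-name styles for emitted VCFs, keyed by style name; each maps
#: a canonical chromosome id to the name written in the file.
CHROM_STYLES = {
    "Gm": lambda c: f"Gm{int(c):02d}" if c.isdigit() else c,
    "chr": lambda c: f"chr{c}",
    "plain": lambda c: c,
}


@dataclass
class SimConfig:
    """Knobs for one simulated collection; fully reproducible by seed."""

    n_populations: int = 3
    fst: float = 0.2
    n_sites: int = 1000
    n_accessions_per_pop: int = 10
    n_redundant: int = 0
    n_cross_offspring: int = 0
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    seed: int = 0
    n_chromosomes: int = 20

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ParameterError(
                f"ancestral_maf_range must satisfy 0 < lo < hi <= 0.5, "
                f"got ({lo}, {hi})"
            )
        if not 0.0 < self.fst < 1.0:
            raise ParameterError(f"fst must be in (0, 1), got {self.fst}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}"
            )
        for name in ("n_populations", "n_sites", "n_accessions_per_pop",
                     "n_redundant", "n_cross_offspring", "n_chromosomes"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def _make_sites(rng: np.random.Generator, n_sites: int, n_chrom: int) -> list[SiteKey]:
    sites = []
    pos_counter = np.zeros(max(n_chrom, 1), dtype=np.int64)
    for i in range(n_sites):
        c = i % max(n_chrom, 1)
        pos_counter[c] += int(rng.integers(100, 10_000))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        sites.append(SiteKey(str(c + 1), int(pos_counter[c]), str(ref), str(alt)))
    return sites


def simulate_collection(config: SimConfig) -> tuple[GenotypeTable, dict]:
    """Simulate a germplasm collection and its ground truth.

    Returns ``(table, truth)`` where ``truth`` maps each accession label
    to ``{"population": str | None, "parents": [str, str] | None,
    "copy_of": str | None}``. Population members are named
    ``P<k>_A<j>``, cross offspring ``CROSS<j>``, redundant copies
    ``<source>_dup<j>``.
    """
    rng = np.random.default_rng(config.seed)
    sites = _make_sites(rng, config.n_sites, config.n_chromosomes)
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_sites)

    f = config.fst
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f

    columns: list[np.ndarray] = []
    labels: list[str] = []
    groups: dict[str, str] = {}
    truth: dict[str, dict] = {}

    for k in range(config.n_populations):
        p_pop = rng.beta(a, b)
        for j in range(config.n_accessions_per_pop):
            label = f"P{k + 1}_A{j + 1}"
            columns.append(rng.binomial(2, p_pop).astype(np.int8))
            labels.append(label)
            groups[label] = f"pop{k + 1}"
            truth[label] = {"population": f"pop{k + 1}", "parents": None,
                            "copy_of": None}

    base_n = len(labels)
    for j in range(config.n_cross_offspring):
        if base_n < 2:
            raise ParameterError("cross offspring need >= 2 base accessions")
        i1, i2 = rng.choice(base_n, size=2, replace=False)
        g1 = (rng.random(config.n_sites) < columns[i1] / 2.0).astype(np.int8)
        g2 = (rng.random(config.n_sites) < columns[i2] / 2.0).astype(np.int8)
        label = f"CROSS{j + 1}"
        columns.append(g1 + g2)
        labels.append(label)
        groups[label] = "cross"
        truth[label] = {
            "population": None,
            "parents": [labels[i1], labels[i2]],
            "copy_of": None,
        }

    for j in range(config.n_redundant):
        if base_n < 1:
            raise ParameterError("redundant copies need >= 1 base accession")
        src = int(rng.integers(base_n))
        label = f"{labels[src]}_dup{j + 1}"
        columns.append(columns[src].copy())
        labels.append(label)
        groups[label] = groups[labels[src]]
        truth[label] = {
            "population": truth[labels[src]]["population"],
            "parents": None,
            "copy_of": labels[src],
        }

    dosages = np.column_stack(columns) if columns else np.zeros((config.n_sites, 0), np.int8)
    if config.missing_rate > 0 and dosages.size:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = np.where(mask, np.int8(MISSING), dosages)

    table = GenotypeTable(sites=sites, accessions=labels, dosages=dosages,
                          groups=groups)
    return table, truth


def write_query_vcf(table: GenotypeTable, accession: str, path: str | Path,
                    chrom_style: str = "Gm") -> None:
    """Write one accession as a single-sample, variant-only VCF.

    Records are emitted only for sites with dosage >= 1 (``0/1`` or
    ``1/1``) or MISSING (``./.``); hom-ref sites are omitted, exactly as
    a variant-only caller would.
    """
    if accession not in table.accessions:
        raise ParameterError(
            f"unknown accession {accession!r}; available: {table.accessions[:10]}..."
        )
    if chrom_style not in CHROM_STYLES:
        raise ParameterError(
            f"chrom_style must be one of {sorted(CHROM_STYLES)}, got {chrom_style!r}"
        )
    style = CHROM_STYLES[chrom_style]
    col = table.accessions.index(accession)
    dosages = table.dosages[:, col]

    contigs: list[str] = []
    for s in table.sites:
        name = style(s.chrom)
        if name not in contigs:
            contigs.append(name)

    gt_of = {1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genopanel-synthetic\n")
        for name in contigs:
            fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{accession}\n")
        # group by contig, sorted by position, so the file is caller-like
        order = sorted(
            range(len(table.sites)),
            key=lambda i: (contigs.index(style(table.sites[i].chrom)),
                           table.sites[i].pos),
        )
        for i in order:
            s = table.sites[i]
            d = int(dosages[i])
            if d == 0:
                continue
            fh.write(
                f"{style(s.chrom)}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\tGT\t"
                f"{gt_of[d]}\n"
            )
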