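"""Readers and writers for genotype tables and serialized panels.

Genotype tables come in two dialects:

* TSV: header row ``chrom  pos  ref  alt  <label1> <label2> ...`` with
  dosage cells in ``{0, 1, 2, NA}``;
* multi-sample VCF v4.x (plain or bgzip): GT field only, biallelic SNP
  records; multiallelic and non-SNP records are dropped at ingestion.

A serialized panel (``.v2g``) is a single uncompressed ZIP archive:
``metadata.json`` (format version, parameters, explained-variance ratios,
labels, groups, provenance) plus delimited text blocks ``sites.tsv``,
``site_means.txt``, ``loadings.tsv`` and ``scores.tsv``. Floats are
written with 17 significant digits so a load/save cycle is bit-exact.
"""

from __future__ import annotations

import io as _io
import json
import logging
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .chromnames import normalize_chrom
from .errors import InputFormatError, PanelVersionError
from .panel_builder import (
    MISSING,
    GenotypeTable,
    PanelModel,
    ReferencePanel,
    SiteKey,
)

log = logging.getLogger(__name__)

PANEL_FORMAT_VERSION = "1"
_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# genotype table ingestion
# ---------------------------------------------------------------------------

def read_genotype_tsv(path: str | Path, aliases: dict[str, str] | None = None) -> GenotypeTable:
    """Read the TSV genotype dialect into a :class:`GenotypeTable`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != required:
        raise InputFormatError(
            f"genotype TSV must start with columns {required}, "
            f"got {list(df.columns[:4])}"
        )
    labels = list(df.columns[4:])
    if not labels:
        raise InputFormatError("genotype TSV has no accession columns")
    sites = [
        SiteKey(normalize_chrom(c, aliases), int(p), r, a)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    cells = df[labels].to_numpy(dtype=object)
    dosages = np.empty(cells.shape, dtype=np.int8)
    valid = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING, ".": MISSING}
    try:
        for (i, j), v in np.ndenumerate(cells):
            dosages[i, j] = valid[v.strip()]
    except KeyError as exc:
        raise InputFormatError(
            f"bad genotype cell {exc.args[0]!r}; expected 0/1/2/NA"
        ) from None
    return GenotypeTable(sites=sites, accessions=labels, dosages=dosages)


def write_genotype_tsv(table: GenotypeTable, path: str | Path) -> None:
    """Write a table in the TSV dialect (missing cells as ``NA``)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt", *table.accessions]) + "\n")
        for i, s in enumerate(table.sites):
            row = [
                "NA" if d == MISSING else str(int(d)) for d in table.dosages[i]
            ]
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t" + "\t".join(row) + "\n")


def read_genotype_vcf(path: str | Path, aliases: dict[str, str] | None = None) -> GenotypeTable:
    """Read a multi-sample VCF into a :class:`GenotypeTable`.

    Only biallelic SNP records are kept; gt_types UNKNOWN (half-calls,
    no-calls) become MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    labels = list(vcf.samples)
    if not labels:
        raise InputFormatError(f"{path}: VCF has no sample columns")
    sites: list[SiteKey] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    # gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
    code = np.array([0, 1, 2, MISSING], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        sites.append(
            SiteKey(normalize_chrom(v.CHROM, aliases), v.POS, v.REF, v.ALT[0])
        )
        rows.append(code[v.gt_types])
    if n_skipped:
        log.info("dropped %d multiallelic/non-SNP records from %s", n_skipped, path)
    if not sites:
        raise InputFormatError(f"{path}: no usable biallelic SNP records")
    return GenotypeTable(
        sites=sites, accessions=labels, dosages=np.vstack(rows)
    )


def read_genotype_table(path: str | Path, aliases: dict[str, str] | None = None) -> GenotypeTable:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` vs TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return read_genotype_vcf(path, aliases)
    return read_genotype_tsv(path, aliases)


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``label<TAB>group`` file (no header)."""
    groups: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputFormatError(f"bad group line {line!r}; expected label<TAB>group")
        groups[parts[0]] = parts[1]
    return groups


# ---------------------------------------------------------------------------
# panel serialization
# ---------------------------------------------------------------------------

def _dump_array(arr: np.ndarray) -> str:
    buf = _io.StringIO()
    np.savetxt(buf, np.atleast_2d(arr), fmt=_FLOAT_FMT, delimiter="\t")
    return buf.getvalue()


def _load_array(text: str, ndim: int) -> np.ndarray:
    arr = np.loadtxt(_io.StringIO(text), delimiter="\t", ndmin=2, dtype=np.float64)
    return arr.ravel() if ndim == 1 else arr


def save_panel(panel: ReferencePanel, path: str | Path) -> None:
    """Write a panel archive; loading it back is bit-exact."""
    meta = {
        "format_version": PANEL_FORMAT_VERSION,
        "maf_threshold": panel.model.maf_threshold,
        "n_components": panel.model.n_components,
        "evr": [float(v) for v in panel.model.evr],
        "labels": panel.labels,
        "groups": panel.groups,
        "provenance": panel.provenance,
    }
    sites_txt = "".join(
        f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\n" for s in panel.model.sites
    )
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        zf.writestr("metadata.json", json.dumps(meta, indent=1))
        zf.writestr("sites.tsv", sites_txt)
        zf.writestr("site_means.txt", _dump_array(panel.model.site_means))
        zf.writestr("loadings.tsv", _dump_array(panel.model.loadings))
        zf.writestr("scores.tsv", _dump_array(panel.scores))


def load_panel(path: str | Path) -> ReferencePanel:
    """Load a panel archive written by :func:`save_panel`."""
    try:
        zf = zipfile.ZipFile(path)
    except (zipfile.BadZipFile, FileNotFoundError) as exc:
        raise InputFormatError(f"{path}: not a panel archive ({exc})") from None
    with zf:
        try:
            meta = json.loads(zf.read("metadata.json"))
        except KeyError:
            raise InputFormatError(f"{path}: panel archive lacks metadata.json") from None
        version = str(meta.get("format_version"))
        if version != PANEL_FORMAT_VERSION:
            raise PanelVersionError(
                f"{path}: panel format version {version!r} is not supported "
                f"(this build reads version {PANEL_FORMAT_VERSION!r})"
            )
        sites = []
        for line in zf.read("sites.tsv").decode().splitlines():
            c, p, r, a = line.split("\t")
            sites.append(SiteKey(c, int(p), r, a))
        site_means = _load_array(zf.read("site_means.txt").decode(), ndim=1)
        loadings = _load_array(zf.read("loadings.tsv").decode(), ndim=2)
        scores = _load_array(zf.read("scores.tsv").decode(), ndim=2)
    model = PanelModel(
        sites=sites,
        site_means=site_means,
        loadings=loadings,
        evr=np.asarray(meta["evr"], dtype=np.float64),
        maf_threshold=float(meta["maf_threshold"]),
        n_components=int(meta["n_components"]),
    )
    return ReferencePanel(
        model=model,
        scores=scores,
        labels=list(meta["labels"]),
        groups=meta.get("groups"),
        provenance=meta.get("provenance", ""),
    )
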