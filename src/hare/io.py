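"""File formats and the SNP-baseline preparation.

Tables travel as plain TSV: haplotype panels in long form
``(line_id, range_id, haplotype_id)``, reference ranges as BED (0-based,
half-open), expression/phenotype matrices as line x column TSV, HARE
matrices in long form with per-cell provenance. SNP genotypes are allele
dosages in {0, 1, 2} (heterozygotes tolerated with a warning for inbred
panels) read from VCF (via cyvcf2) or TSV; positions are 1-based on disk
(VCF convention) and 0-based internally. ``maf_filter`` and ``ld_prune``
implement the SNP-baseline preparation: drop sites with minor allele
frequency <= 0.05, then greedily drop sites whose squared correlation with
a retained site within 100 kb exceeds 0.9.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InputError
from .effects import ESTIMATED, HareMatrix
from .haplo import MISSING, HaplotypePanel, ReferenceRange


# ---------------------------------------------------------------------------
# haplotype panels and ranges
# ---------------------------------------------------------------------------

def write_haplotypes_tsv(panel: HaplotypePanel, path: str | Path) -> None:
    """Long-form TSV (line_id, range_id, haplotype_id); missing cells skipped."""
    long = (
        panel.assignments.rename_axis("line_id")
        .reset_index()
        .melt(id_vars="line_id", var_name="range_id", value_name="haplotype_id")
    )
    long = long[long["haplotype_id"] != MISSING]
    long.to_csv(path, sep="\t", index=False)


def read_haplotypes_tsv(path: str | Path) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "range_id": str})
    required = {"line_id", "range_id", "haplotype_id"}
    if not required.issubset(df.columns):
        raise InputError(
            f"{path}: haplotype table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    if df["haplotype_id"].isna().any():
        row = int(df.index[df["haplotype_id"].isna()][0]) + 2
        raise InputError(f"{path}: missing haplotype_id at line {row}")
    # preserve first-appearance order for lines and ranges
    lines = pd.unique(df["line_id"])
    ranges = pd.unique(df["range_id"])
    table = df.pivot(index="line_id", columns="range_id", values="haplotype_id")
    table = table.reindex(index=lines, columns=ranges).fillna(MISSING)
    return HaplotypePanel(table)


def write_ranges_bed(ranges: list[ReferenceRange], path: str | Path) -> None:
    """BED with name = range_id and score 1/0 flagging genic ranges."""
    with open(path, "w") as fh:
        for r in ranges:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.range_id}\t{int(r.genic)}\n")


def read_ranges_bed(path: str | Path) -> list[ReferenceRange]:
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.split("\t")
            if len(parts) < 4:
                raise InputError(f"{path}:{ln}: BED needs >= 4 columns (chrom, start, end, name)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: non-integer coordinates") from exc
            genic = True
            if len(parts) >= 5 and parts[4] not in (".", ""):
                genic = bool(int(float(parts[4])))
            out.append(ReferenceRange(parts[3], parts[0], start, end, genic))
    return out


# ---------------------------------------------------------------------------
# numeric matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "line_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path, index_col: str = "line_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={index_col: str})
    if index_col not in df.columns:
        raise InputError(f"{path}: expected index column '{index_col}'")
    df = df.set_index(index_col)
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise InputError(
            f"{path}: non-numeric cell at line_id={df.index[i]!r}, "
            f"column={df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    return num


read_expression_tsv = read_matrix_tsv
write_expression_tsv = write_matrix_tsv
read_phenotypes_tsv = read_matrix_tsv
write_phenotypes_tsv = write_matrix_tsv


# ---------------------------------------------------------------------------
# HARE matrices
# ---------------------------------------------------------------------------

def write_hare_tsv(hare: HareMatrix, path: str | Path) -> None:
    rows = []
    for g in hare.genes:
        for h in hare.effects.columns:
            rows.append(
                {
                    "gene_id": g,
                    "haplotype_id": int(h),
                    "effect": hare.effects.at[g, h],
                    "provenance": hare.provenance.at[g, h],
                    "mu": hare.mu[g],
                }
            )
    out = pd.DataFrame(rows)
    out["model"] = hare.model
    out["tissue"] = hare.tissue if hare.tissue is not None else ""
    out.to_csv(path, sep="\t", index=False)


def read_hare_tsv(path: str | Path) -> HareMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "haplotype_id", "effect", "provenance", "mu"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: HARE table needs columns {sorted(required)}")
    eff = df.pivot(index="gene_id", columns="haplotype_id", values="effect")
    prov = df.pivot(index="gene_id", columns="haplotype_id", values="provenance")
    genes = pd.unique(df["gene_id"])
    eff, prov = eff.loc[genes], prov.loc[genes]
    mu = df.drop_duplicates("gene_id").set_index("gene_id")["mu"].loc[genes]
    model = int(df["model"].iloc[0]) if "model" in df.columns else 3
    tissue = None
    if "tissue" in df.columns and isinstance(df["tissue"].iloc[0], str) and df["tissue"].iloc[0]:
        tissue = df["tissue"].iloc[0]
    eff.index.name = prov.index.name = mu.index.name = "gene"
    return HareMatrix(effects=eff, mu=mu, provenance=prov, model=model, tissue=tissue)


# ---------------------------------------------------------------------------
# SNP matrices
# ---------------------------------------------------------------------------

@dataclass
class SnpMatrix:
    """Line x site allele-dosage matrix with site metadata.

    ``dosages`` holds {0, 1, 2} (NaN = missing call); ``sites`` is indexed
    by site id with columns chrom, pos (0-based internally), ref, alt.
    """

    dosages: pd.DataFrame
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise InputError(
                f"dosage outside {{0,1,2}} at line={self.dosages.index[i]!r}, "
                f"site={self.dosages.columns[j]!r}"
            )
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise InputError(
                    f"positions not strictly increasing on chrom {chrom}"
                )

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def subset_sites(self, site_ids) -> "SnpMatrix":
        return SnpMatrix(self.dosages.loc[:, site_ids], self.sites.loc[site_ids])

    def to_feature_matrix(self) -> pd.DataFrame:
        """Mean-impute missing calls (features must be complete)."""
        d = self.dosages.copy()
        return d.fillna(d.mean(axis=0))


def read_vcf(path: str | Path) -> SnpMatrix:
    """Read genotypes from a VCF into dosages (requires cyvcf2).

    Heterozygous calls in an inbred panel are accepted as dosage 1 with a
    warning; missing calls become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta, ids = [], [], []
    n_het = 0
    for var in vcf:
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dose = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        n_het += int((gt == 1).sum())
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ids.append(sid)
        rows.append(dose)
        meta.append(
            {"chrom": var.CHROM, "pos": var.POS - 1, "ref": var.REF,
             "alt": var.ALT[0] if var.ALT else "."}
        )
    if n_het:
        warnings.warn(f"{n_het} heterozygous calls in an inbred panel (dosage 1)", stacklevel=2)
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    sites = pd.DataFrame(meta, index=pd.Index(ids, name="site_id"))
    return SnpMatrix(dosages=dosages, sites=sites)


def write_snp_tsv(snps: SnpMatrix, prefix: str | Path) -> tuple[Path, Path]:
    geno = Path(f"{prefix}.dosages.tsv")
    sites = Path(f"{prefix}.sites.tsv")
    snps.dosages.to_csv(geno, sep="\t", index_label="line_id")
    snps.sites.to_csv(sites, sep="\t", index_label="site_id")
    return geno, sites


def read_snp_tsv(geno_path: str | Path, sites_path: str | Path) -> SnpMatrix:
    dos = read_matrix_tsv(geno_path)
    sites = pd.read_csv(sites_path, sep="\t", dtype={"site_id": str, "chrom": str})
    if "site_id" not in sites.columns:
        raise InputError(f"{sites_path}: expected a 'site_id' column")
    sites = sites.set_index("site_id")
    if list(dos.columns) != list(sites.index):
        raise InputError("dosage columns and site metadata disagree")
    return SnpMatrix(dosages=dos, sites=sites)


def maf_filter(snps: SnpMatrix, min_maf: float = 0.05) -> SnpMatrix:
    """Drop sites whose minor allele frequency is <= ``min_maf``.

    The threshold is strict ("higher than 0.05" retained), so a site at
    exactly 0.05 is removed; monomorphic sites always are.
    """
    d = snps.dosages.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > min_maf
    if not keep.any():
        warnings.warn("MAF filter removed every site", stacklevel=2)
    return snps.subset_sites(snps.dosages.columns[keep])


def ld_prune(
    snps: SnpMatrix, r2_max: float = 0.9, window_bp: int = 100_000
) -> SnpMatrix:
    """Greedy left-to-right LD pruning per chromosome.

    A site is dropped when its squared Pearson correlation with any already
    retained site within ``window_bp`` upstream exceeds ``r2_max``. The scan
    order (ascending position) makes the output deterministic.
    """
    d = snps.dosages
    filled = d.fillna(d.mean(axis=0)).to_numpy(dtype=float)
    cols = list(d.columns)
    pos = snps.sites["pos"].to_numpy()
    chrom = snps.sites["chrom"].to_numpy()
    keep_ids: list[str] = []
    for ch in pd.unique(chrom):
        idx = np.flatnonzero(chrom == ch)  # already in ascending position
        kept: list[int] = []
        for j in idx:
            xj = filled[:, j]
            sj = xj.std()
            drop = False
            for k in reversed(kept):
                if pos[j] - pos[k] > window_bp:
                    break
                xk = filled[:, k]
                sk = xk.std()
                if sj == 0 or sk == 0:
                    continue
                r = float(np.corrcoef(xj, xk)[0, 1])
                if r * r > r2_max:
                    drop = True
                    break
            if not drop:
                kept.append(j)
        keep_ids.extend(cols[j] for j in kept)
    return snps.subset_sites(keep_ids)


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    seed: int,
    artifacts: dict[str, str | Path],
    extra: dict | None = None,
) -> dict:
    """JSON run manifest: config snapshot, master seed, artifact digests."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "artifacts": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in artifacts.items()
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
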