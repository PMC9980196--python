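"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF with GT and DS FORMAT fields (DS preferred when
reading); tables are tab-separated with a header row, UTF-8, '.' for
missing, no quoting; reports are JSON. Coordinates are 1-based inclusive
(VCF convention) and dates are integer day numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF


def read_vcf_dosages(path):
    """Dosage matrix from a VCF: DS field preferred, GT fallback.

    Multi-allelic records are skipped (counted); missing genotypes are
    np.nan. Returns ``(dosages, variants, sample_ids, n_multiallelic)``
    with ``variants`` columns id, chrom, pos, ref, alt.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where((d < -0.5) | ~np.isfinite(d), np.nan, d)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = rec.gt_types.astype(float)
            d = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(d)
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", str(rec.CHROM), rec.POS, rec.REF, rec.ALT[0]))
    vcf.close()
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    return dosages, variants, samples, n_multi


def write_vcf(path, dosages: np.ndarray, variants: pd.DataFrame, sample_ids) -> None:
    """Minimal biallelic VCF with GT (hard call) and DS (dosage) fields."""
    path = Path(path)
    n, m = dosages.shape
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].astype(str).to_numpy()))
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n')
        for c in sorted(set(variants["chrom"].astype(str)), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for j in order:
            v = variants.iloc[j]
            cells = []
            for i in range(n):
                d = dosages[i, j]
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    gt = gt_map[float(np.clip(np.rint(d), 0, 2))]
                    cells.append(f"{gt}:{d:g}")
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\tPASS\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_whitelist(path) -> set[str]:
    """One variant id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write a synthetic cohort's artifacts to a directory.

    Produces genotypes.vcf, variants.tsv, weights.tsv, dispensing.tsv,
    ect.tsv and truth.tsv (truth is reference material for evaluation
    only — the pipeline never reads it). Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.vcf",
        "variants": outdir / "variants.tsv",
        "weights": outdir / "weights.tsv",
        "dispensing": outdir / "dispensing.tsv",
        "ect": outdir / "ect.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(paths["genotypes"], cohort.dosages, cohort.variants, cohort.sample_ids)
    write_tsv(cohort.variants, paths["variants"])
    write_tsv(cohort.weights, paths["weights"])
    write_tsv(cohort.dispensing, paths["dispensing"])
    write_tsv(cohort.ect, paths["ect"])
    write_tsv(cohort.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
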