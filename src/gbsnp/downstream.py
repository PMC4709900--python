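"""Step 8: exports of the final genotyping matrix plus replicate similarity.

The numeric matrix recodes calls as 0 (primary homozygote), 0.5 (heterozygote),
1 (secondary homozygote) and NA (missing) for diversity analyses; HapMap and
PLINK transposed-PED writers cover the common association toolkits. Replicate
consistency is quantified with a modified Gower coefficient of similarity,

    S(x, y) = sum_i s_i * w_i / sum_i w_i

where s_i is 1 for identical genotypes, 0.5 when they differ by one allele
(heterozygote vs either homozygote) and 0 for opposite homozygotes, and w_i is
1 only when both genotypes are scored at SNP i.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_calling import (
    GenotypeCall,
    HET,
    HOM_PRIMARY,
    HOM_SECONDARY,
    MISSING,
    SNPRecord,
)

_NUMERIC = {HOM_PRIMARY: 0.0, HET: 0.5, HOM_SECONDARY: 1.0, MISSING: np.nan}


def to_numeric_matrix(
    records: Sequence[SNPRecord], genotype_ids: Sequence[str]
) -> pd.DataFrame:
    """SNPs x genotypes DataFrame of 0 / 0.5 / 1 codes with NaN for missing."""
    index = [f"{r.ref_id}_{r.pos}" for r in records]
    data = np.full((len(records), len(genotype_ids)), np.nan)
    for i, r in enumerate(records):
        for g, call in enumerate(r.calls):
            data[i, g] = _NUMERIC[call.state]
    return pd.DataFrame(data, index=index, columns=list(genotype_ids))


def write_numeric_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="snp_id")


_HAPMAP_FIXED = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
    "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def to_hapmap(records: Sequence[SNPRecord], genotype_ids: Sequence[str]) -> pd.DataFrame:
    """HapMap table: 11 fixed columns then one diploid base-pair per genotype.

    Heterozygotes are written primary-then-secondary base; missing is 'NN'.
    """
    rows = []
    for r in records:
        fixed = [
            f"{r.ref_id}_{r.pos}", f"{r.primary_allele}/{r.secondary_allele}",
            r.ref_id, r.pos, "+", "NA", "NA", "NA", "NA", "NA", "NA",
        ]
        geno = []
        for call in r.calls:
            if call.state == HOM_PRIMARY:
                geno.append(r.primary_allele * 2)
            elif call.state == HET:
                geno.append(r.primary_allele + r.secondary_allele)
            elif call.state == HOM_SECONDARY:
                geno.append(r.secondary_allele * 2)
            else:
                geno.append("NN")
        rows.append(fixed + geno)
    return pd.DataFrame(rows, columns=_HAPMAP_FIXED + list(genotype_ids))


def write_hapmap(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def to_plink_transposed(
    records: Sequence[SNPRecord], genotype_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PLINK transposed files: (TPED, TFAM).

    TPED rows carry chrom, SNP id, genetic distance 0, position, then two
    allele columns per genotype ('0 0' when missing). TFAM uses the genotype
    id as family id with parents 0, sex 0, phenotype -9.
    """
    tped_rows = []
    for r in records:
        row = [r.ref_id, f"{r.ref_id}_{r.pos}", 0, r.pos]
        for call in r.calls:
            if call.state == HOM_PRIMARY:
                row += [r.primary_allele, r.primary_allele]
            elif call.state == HET:
                row += [r.primary_allele, r.secondary_allele]
            elif call.state == HOM_SECONDARY:
                row += [r.secondary_allele, r.secondary_allele]
            else:
                row += ["0", "0"]
        tped_rows.append(row)
    allele_cols = [f"{g}_{a}" for g in genotype_ids for a in (1, 2)]
    tped = pd.DataFrame(tped_rows, columns=["chrom", "snp_id", "cm", "pos"] + allele_cols)
    tfam = pd.DataFrame(
        {
            "fid": list(genotype_ids),
            "iid": list(genotype_ids),
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    return tped, tfam


def write_plink(tped: pd.DataFrame, tfam: pd.DataFrame, tped_path, tfam_path) -> None:
    tped.to_csv(tped_path, sep="\t", index=False, header=False)
    tfam.to_csv(tfam_path, sep="\t", index=False, header=False)


def _pair_score(a: GenotypeCall, b: GenotypeCall) -> float:
    if a.state == b.state:
        return 1.0
    if HET in (a.state, b.state):
        return 0.5  # differ by one allele
    return 0.0  # opposite homozygotes


def gower_similarity(
    x: Sequence[GenotypeCall], y: Sequence[GenotypeCall]
) -> float:
    """Modified Gower coefficient over two equal-length call vectors.

    SNPs where either call is missing get weight 0; raises ValueError when no
    SNP is co-genotyped (the coefficient is undefined, not 0).
    """
    if len(x) != len(y):
        raise ValueError("call vectors must cover the same SNP list")
    num = den = 0.0
    for a, b in zip(x, y):
        if a.state == MISSING or b.state == MISSING:
            continue
        num += _pair_score(a, b)
        den += 1.0
    if den == 0:
        raise ValueError("no co-genotyped SNPs: Gower similarity undefined")
    return num / den


def replicate_report(
    records: Sequence[SNPRecord],
    genotype_ids: Sequence[str],
    id_a: str,
    id_b: str,
) -> tuple[float, float]:
    """(Gower similarity, % exact genotype matches) for two genotype columns,
    computed over SNPs scored in both."""
    for gid in (id_a, id_b):
        if gid not in genotype_ids:
            raise KeyError(f"unknown genotype id {gid!r}")
    ia, ib = genotype_ids.index(id_a), genotype_ids.index(id_b)
    x = [r.calls[ia] for r in records]
    y = [r.calls[ib] for r in records]
    gower = gower_similarity(x, y)
    shared = [
        (a.state, b.state)
        for a, b in zip(x, y)
        if a.state != MISSING and b.state != MISSING
    ]
    exact = sum(1 for a, b in shared if a == b)
    return gower, 100.0 * exact / len(shared)
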