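"""Readers/writers for standard formats, region grouping, and the CLI.

Supported inputs: VCF 4.x with GT fields (biallelic records; multi-allelic
sites are skipped with a warning), PLINK-style .ped/.map text with an
optional .fam-style pedigree companion for VCFs, BED regions (0-based
half-open, converted to 1-based inclusive internally) with an optional
flanking extension, and TSV phenotype/covariate tables.  Genotype scores
are oriented to the minor allele, determined on founders for trio designs
and on all subjects otherwise (ties at MAF 0.5 break by lexicographic
allele name).
"""

from __future__ import annotations

import logging
import sys
import warnings
from dataclasses import dataclass, field

import click
import numpy as np
import pandas as pd

from . import artp, burden as burden_mod, simpop
from .pervariant import (
    GenotypeMatrix,
    MISSING,
    PhenotypeTable,
    TrioSet,
)

logger = logging.getLogger("adabf")

__all__ = [
    "RegionSet",
    "read_genotypes",
    "read_phenotypes",
    "read_regions_bed",
    "map_variants_to_regions",
    "write_vcf",
    "write_ped",
    "main",
]


@dataclass
class RegionSet:
    """Gene/region definitions with optional flanking extension.

    Coordinates are 1-based inclusive internally; BED input (0-based
    half-open) is converted on read.  ``members`` maps region ids to the
    variant ids assigned by :func:`map_variants_to_regions`.
    """

    frame: pd.DataFrame  # columns: region, chrom, start, end
    flank: int = 0
    members: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"region", "chrom", "start", "end"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"region table needs columns {sorted(need)}")
        if (self.frame["start"] > self.frame["end"]).any():
            raise ValueError("region start must be <= end")


def _normalize_chrom(values) -> np.ndarray:
    return np.array([str(v).removeprefix("chr") for v in values], dtype=object)


def read_regions_bed(path, flank: int = 0) -> RegionSet:
    """BED (chrom, start, end, name); 0-based half-open -> 1-based inclusive."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        bed[3] = [f"region{i + 1}" for i in range(len(bed))]
    frame = pd.DataFrame({
        "region": bed[3].astype(str),
        "chrom": _normalize_chrom(bed[0]),
        "start": bed[1].astype(np.int64) + 1,
        "end": bed[2].astype(np.int64),
    })
    return RegionSet(frame=frame, flank=flank)


def map_variants_to_regions(gm: GenotypeMatrix, regions: RegionSet, flank: int | None = None) -> RegionSet:
    """Assign variants to regions: position in [start - flank, end + flank].

    The interval is closed on both ends; a variant may belong to several
    regions.  Chromosome names are normalized ("chr1" == "1") with a
    warning when conventions differ.
    """
    if gm.chrom is None or gm.pos is None:
        raise ValueError("genotype matrix lacks chrom/pos metadata")
    flank = regions.flank if flank is None else flank
    vchrom = _normalize_chrom(gm.chrom)
    if not np.array_equal(vchrom, np.asarray(gm.chrom, dtype=object)):
        warnings.warn("normalized 'chr' prefixes on variant chromosome names", stacklevel=2)
    pos = np.asarray(gm.pos, dtype=np.int64)
    members = {}
    for row in regions.frame.itertuples(index=False):
        lo, hi = row.start - flank, row.end + flank
        sel = (vchrom == row.chrom) & (pos >= lo) & (pos <= hi)
        members[row.region] = list(gm.variant_ids[sel])
    return RegionSet(frame=regions.frame.copy(), flank=flank, members=members)


def read_phenotypes(path, outcome: str = "phenotype", covariates=()) -> PhenotypeTable:
    frame = pd.read_csv(path, sep="\t")
    return PhenotypeTable(frame=frame, outcome=outcome, covariates=tuple(covariates))


# ---------------------------------------------------------------------------
# Genotype formats
# ---------------------------------------------------------------------------


def _read_pedigree_table(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype=str)
    return ped


def _trios_from_pedigree(ped: pd.DataFrame, sample_ids: np.ndarray) -> tuple[TrioSet | None, np.ndarray]:
    """Trio triples (father, mother, child) and per-sample role flags."""
    index = {s: i for i, s in enumerate(sample_ids)}
    roles = np.array(["unrelated"] * len(sample_ids), dtype=object)
    triples = []
    for row in ped.itertuples(index=False):
        if row.iid not in index:
            continue
        if row.father in index and row.mother in index and row.father != "0" and row.mother != "0":
            f, m, c = index[row.father], index[row.mother], index[row.iid]
            triples.append((f, m, c))
            roles[f] = roles[m] = "founder"
            roles[c] = "offspring"
    for row in ped.itertuples(index=False):  # untyped-parent members stay founders
        if row.iid in index and roles[index[row.iid]] == "unrelated":
            roles[index[row.iid]] = "founder"
    trios = TrioSet(np.array(triples)) if triples else None
    return trios, roles


def _orient_minor(scores: np.ndarray, ref: np.ndarray, alt: np.ndarray, roles: np.ndarray):
    """Flip columns so scores count the minor allele (founder-based MAF)."""
    founder = roles == "founder"
    if not founder.any():
        founder = np.ones(scores.shape[0], dtype=bool)
    g = scores[founder].astype(float)
    g[g == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(g, axis=0) / 2.0
    freq = np.nan_to_num(freq, nan=0.0)
    minor = alt.copy()
    major = ref.copy()
    flip = (freq > 0.5) | ((freq == 0.5) & (ref < alt))  # tie: lexicographic
    for j in np.where(flip)[0]:
        col = scores[:, j]
        nonmiss = col != MISSING
        scores[nonmiss, j] = 2 - col[nonmiss]
        minor[j], major[j] = major[j], minor[j]
    return scores, minor, major


def _read_vcf(path, pedigree=None):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.array(vcf.samples, dtype=object)
    rows, ids, refs, alts, chroms, poss = [], [], [], [], [], []
    seen = set()
    for v in vcf:
        if len(v.ALT) != 1 or v.ALT[0] in ("*", "."):
            warnings.warn(f"skipping non-biallelic record at {v.CHROM}:{v.POS}", stacklevel=2)
            continue
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if vid in seen:
            raise ValueError(f"duplicate variant id {vid!r}")
        seen.add(vid)
        gt = v.gt_types.astype(np.int8)  # 0/1/2 ALT copies, 3 unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
        ids.append(vid)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        chroms.append(v.CHROM)
        poss.append(v.POS)
    if not rows:
        raise ValueError("no biallelic variants in VCF")
    scores = np.column_stack(rows).astype(np.int8)

    trios, roles = (None, np.array(["unrelated"] * len(samples), dtype=object))
    if pedigree is not None:
        trios, roles = _trios_from_pedigree(_read_pedigree_table(pedigree), samples)
    scores, minor, major = _orient_minor(scores, np.array(refs, dtype=object),
                                         np.array(alts, dtype=object), roles)
    gm = GenotypeMatrix(
        genotypes=scores, variant_ids=np.array(ids, dtype=object),
        minor_alleles=minor, major_alleles=major, roles=roles,
        sample_ids=samples, chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
    )
    return gm, trios


def _read_plink_text(ped_path, map_path):
    mapdf = pd.read_csv(map_path, sep=r"\s+", header=None,
                        names=["chrom", "id", "cm", "pos"], dtype=str)
    if mapdf["id"].duplicated().any():
        raise ValueError("duplicate variant ids in .map")
    L = len(mapdf)
    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    if ped.shape[1] != 6 + 2 * L:
        raise ValueError(f".ped has {ped.shape[1]} columns, expected {6 + 2 * L}")
    samples = ped[1].to_numpy(dtype=object)
    alleles = ped.iloc[:, 6:].to_numpy(dtype=object)
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]

    scores = np.full((len(samples), L), MISSING, dtype=np.int8)
    refs, alts = [], []
    for j in range(L):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = sorted(set(col) - {"0"})
        if len(obs) > 2:
            raise ValueError(f"variant {mapdf['id'][j]} is not biallelic")
        ref = obs[0] if obs else "N"
        alt = obs[1] if len(obs) > 1 else ref
        refs.append(ref)
        alts.append(alt)
        missing = (a1[:, j] == "0") | (a2[:, j] == "0")
        cnt = (a1[:, j] == alt).astype(np.int8) + (a2[:, j] == alt).astype(np.int8)
        scores[:, j] = np.where(missing, MISSING, cnt)

    trios, roles = _trios_from_pedigree(ped.iloc[:, :6].set_axis(
        ["fid", "iid", "father", "mother", "sex", "pheno"], axis=1), samples)
    scores, minor, major = _orient_minor(scores, np.array(refs, dtype=object),
                                         np.array(alts, dtype=object), roles)
    gm = GenotypeMatrix(
        genotypes=scores, variant_ids=mapdf["id"].to_numpy(dtype=object),
        minor_alleles=minor, major_alleles=major, roles=roles, sample_ids=samples,
        chrom=mapdf["chrom"].to_numpy(dtype=object),
        pos=mapdf["pos"].astype(np.int64).to_numpy(),
    )
    return gm, trios


def read_genotypes(path, fmt: str = "vcf", pedigree=None, map_path=None):
    """Load genotypes; returns (GenotypeMatrix, TrioSet | None)."""
    if fmt == "vcf":
        return _read_vcf(path, pedigree=pedigree)
    if fmt == "plink-text":
        if map_path is None:
            map_path = str(path).rsplit(".", 1)[0] + ".map"
        return _read_plink_text(path, map_path)
    raise ValueError("format must be 'vcf' or 'plink-text'")


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 (GT only); REF = major allele, ALT = minor."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.sample_ids)) + "\n")
        codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        chrom = gm.chrom if gm.chrom is not None else ["1"] * gm.n_variants
        pos = gm.pos if gm.pos is not None else np.arange(1, gm.n_variants + 1)
        for j in range(gm.n_variants):
            gts = "\t".join(codes[int(g)] for g in gm.genotypes[:, j])
            fh.write(f"{chrom[j]}\t{int(pos[j])}\t{gm.variant_ids[j]}\t"
                     f"{gm.major_alleles[j]}\t{gm.minor_alleles[j]}\t.\t.\t.\tGT\t{gts}\n")


def write_pedigree(gm: GenotypeMatrix, trios: TrioSet | None, path) -> None:
    """Write a .fam-style pedigree companion for a VCF."""
    father = {c: f for f, m, c in (trios.trios if trios is not None else [])}
    mother = {c: m for f, m, c in (trios.trios if trios is not None else [])}
    fam_of = {}
    if trios is not None:
        for t, (f, m, c) in enumerate(trios.trios):
            fam_of[f] = fam_of[m] = fam_of[c] = f"FAM{t + 1}"
    with open(path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fid = fam_of.get(i, f"U{i + 1}")
            fa = gm.sample_ids[father[i]] if i in father else "0"
            mo = gm.sample_ids[mother[i]] if i in mother else "0"
            pheno = "2" if gm.roles[i] == "offspring" else "0"
            fh.write(f"{fid} {sid} {fa} {mo} 0 {pheno}\n")


def write_ped(gm: GenotypeMatrix, trios: TrioSet | None, ped_path, map_path) -> None:
    """PLINK-style .ped/.map text output."""
    chrom = gm.chrom if gm.chrom is not None else ["1"] * gm.n_variants
    pos = gm.pos if gm.pos is not None else np.arange(1, gm.n_variants + 1)
    with open(map_path, "w") as fh:
        for j in range(gm.n_variants):
            fh.write(f"{chrom[j]}\t{gm.variant_ids[j]}\t0\t{int(pos[j])}\n")
    father = {c: f for f, m, c in (trios.trios if trios is not None else [])}
    mother = {c: m for f, m, c in (trios.trios if trios is not None else [])}
    fam_of = {}
    if trios is not None:
        for t, (f, m, c) in enumerate(trios.trios):
            fam_of[f] = fam_of[m] = fam_of[c] = f"FAM{t + 1}"
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fid = fam_of.get(i, f"U{i + 1}")
            fa = gm.sample_ids[father[i]] if i in father else "0"
            mo = gm.sample_ids[mother[i]] if i in mother else "0"
            pheno = "2" if gm.roles[i] == "offspring" else "0"
            fields = [fid, str(sid), str(fa), str(mo), "0", pheno]
            for j in range(gm.n_variants):
                g = int(gm.genotypes[i, j])
                mi, ma = gm.minor_alleles[j], gm.major_alleles[j]
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [mi] * g + [ma] * (2 - g)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _write_per_variant(gm, trios, pheno, design, trait, prior, path) -> None:
    """Per-variant TSV: maf, (b, c for trios), beta, variance, test, BF."""
    from .bayes import wakefield_bf
    from .pervariant import count_transmissions, logistic_effects_table, \
        regression_effects, tdt_effect

    if design == "trio":
        counts = count_transmissions(gm, trios)
        eff = tdt_effect(counts)
    elif trait == "binary" and not pheno.covariates:
        eff = logistic_effects_table(gm.genotypes, pheno.outcome_values(),
                                     variant_ids=gm.variant_ids)
    else:
        eff = regression_effects(gm, pheno, trait=trait)
    table = eff.to_frame()
    if "maf" not in table.columns:
        table.insert(1, "maf", gm.maf())
    if design == "trio":
        table.insert(2, "b", counts.b)
        table.insert(3, "c", counts.c)
    bf = wakefield_bf(eff, prior)
    table["log_bf"] = bf.log_bf
    table["bf"] = bf.bf
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _result_frame(rows) -> pd.DataFrame:
    cols = ["region", "L", "method", "prior_w", "min_p", "adjusted_p", "B_used",
            "selected_k", "selected_variants", "floor", "n_filtered"]
    return pd.DataFrame(rows, columns=cols)


@click.group()
def main() -> None:
    """Gene/region association tests combining Bayes factors adaptively."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(message)s")


@main.command("test")
@click.option("--genotypes", required=True, type=click.Path(exists=True))
@click.option("--format", "fmt", default="vcf", type=click.Choice(["vcf", "plink-text"]))
@click.option("--pedigree", type=click.Path(exists=True), default=None)
@click.option("--phenotypes", type=click.Path(exists=True), default=None)
@click.option("--regions", type=click.Path(exists=True), default=None,
              help="BED file; omit to test all variants as one region")
@click.option("--flank", default=30_000, show_default=True)
@click.option("--design", default="trio", type=click.Choice(["trio", "cc"]))
@click.option("--trait", default="binary", type=click.Choice(["binary", "quantitative"]))
@click.option("--method", default="adabf", type=click.Choice(["adabf", "adabf1", "ada", "burden"]))
@click.option("--prior-sd", default=0.2, show_default=True)
@click.option("--min-resamples", default=100, show_default=True)
@click.option("--max-resamples", default=10_000_000, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
@click.option("--per-variant-out", type=click.Path(), default=None,
              help="also write the per-variant summary TSV (counts, beta, BF)")
def cli_test(genotypes, fmt, pedigree, phenotypes, regions, flank, design, trait,
             method, prior_sd, min_resamples, max_resamples, seed, out,
             per_variant_out) -> None:
    """Run a region-based association test and write a results TSV."""
    from .bayes import PriorSpec
    from .pervariant import count_transmissions

    gm, trios = read_genotypes(genotypes, fmt=fmt, pedigree=pedigree)
    if design == "trio" and trios is None:
        raise click.ClickException("trio design requires a pedigree with complete trios")
    pheno = None
    if design == "cc":
        if phenotypes is None:
            raise click.ClickException("case-control design requires --phenotypes")
        pheno = read_phenotypes(phenotypes)

    if regions is not None:
        rset = map_variants_to_regions(gm, read_regions_bed(regions), flank=flank)
        groups = rset.members
    else:
        groups = {"all": list(gm.variant_ids)}

    prior = None
    if method == "adabf":
        prior = PriorSpec.from_sd(prior_sd, label="ADABF")

    if per_variant_out is not None:
        _write_per_variant(gm, trios, pheno, design, trait,
                           prior or PriorSpec.from_sd(prior_sd), per_variant_out)

    rows = []
    for region_id in sorted(groups):
        vids = groups[region_id]
        if not vids:
            logger.info("region %s: no variants mapped, skipped", region_id)
            continue
        keep = np.isin(gm.variant_ids, vids)
        sub = gm.subset_variants(keep)
        try:
            if method == "burden":
                if design == "trio":
                    counts = count_transmissions(sub, trios)
                    res = burden_mod.burden_test_trio(counts, region_id=region_id)
                else:
                    res = burden_mod.burden_test_unrelated(sub, pheno, trait=trait,
                                                           region_id=region_id)
                rows.append(res.to_row())
            else:
                if design == "trio":
                    res = artp.test_region_trio(sub, trios, method=method, prior=prior,
                                                b_min=min_resamples, b_max=max_resamples,
                                                seed=seed, region_id=region_id)
                else:
                    res = artp.test_region_unrelated(sub, pheno, method=method, prior=prior,
                                                     trait=trait, b_min=min_resamples,
                                                     b_max=max_resamples, seed=seed,
                                                     region_id=region_id)
                logger.info("region %s: L=%d adjusted_p=%.3g B=%d filtered=%d",
                            region_id, res.L, res.adjusted_p, res.b_used, res.n_filtered)
                rows.append(res.to_row())
        except ValueError as exc:
            logger.info("region %s skipped: %s", region_id, exc)
    _result_frame(rows).to_csv(out, sep="\t", index=False, float_format="%.10g")


@main.command("simulate")
@click.option("--design", default="trio", type=click.Choice(["trio", "cc"]))
@click.option("--n-trios", default=2000, show_default=True)
@click.option("--n-cases", default=1000, show_default=True)
@click.option("--n-controls", default=1000, show_default=True)
@click.option("--n-variants", default=150, show_default=True)
@click.option("--n-haplotypes", default=10_000, show_default=True)
@click.option("--ld", default=0.7, show_default=True)
@click.option("--d", "n_causal", default=0, show_default=True, help="number of causal variants")
@click.option("--odds-ratio", default=1.5, show_default=True)
@click.option("--scenario", default="deleterious", type=click.Choice(["deleterious", "mixed"]))
@click.option("--seed", default=0, show_default=True)
@click.option("--prefix", required=True, help="output path prefix")
def cli_simulate(design, n_trios, n_cases, n_controls, n_variants, n_haplotypes,
                 ld, n_causal, odds_ratio, scenario, seed, prefix) -> None:
    """Simulate a dataset (VCF + pedigree/phenotypes) from a synthetic pool."""
    pool = simpop.make_pool(n_sites=n_variants, n_haplotypes=n_haplotypes, ld=ld, seed=seed)
    config = simpop.SimConfig(design=design, n_trios=n_trios, n_cases=n_cases,
                              n_controls=n_controls, d=n_causal,
                              or_magnitude=odds_ratio, scenario=scenario)
    rng = np.random.default_rng(seed + 1)
    if design == "trio":
        gm, trios = simpop.simulate_trios(pool, config, rng=rng)
        write_vcf(gm, f"{prefix}.vcf")
        write_pedigree(gm, trios, f"{prefix}.fam")
        logger.info("wrote %s.vcf and %s.fam (%d trios)", prefix, prefix, len(trios))
    else:
        gm, pheno = simpop.simulate_case_control(pool, config, rng=rng)
        write_vcf(gm, f"{prefix}.vcf")
        pheno.frame.to_csv(f"{prefix}.pheno.tsv", sep="\t", index=False)
        logger.info("wrote %s.vcf and %s.pheno.tsv", prefix, prefix)


@main.command("rank-compare")
@click.option("--n-replicates", default=1000, show_default=True)
@click.option("--n-pools", default=5, show_default=True)
@click.option("--n-cases", default=1000, show_default=True)
@click.option("--n-controls", default=1000, show_default=True)
@click.option("--odds-ratio", default=1.5, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_rank_compare(n_replicates, n_pools, n_cases, n_controls, odds_ratio, seed, out) -> None:
    """Compare the causal variant's rank by Bayes factor vs by P-value."""
    pools = [simpop.make_pool(seed=seed + 1000 + i) for i in range(n_pools)]
    _, summary = simpop.ranking_experiment(pools, n_replicates, seed=seed,
                                           n_cases=n_cases, n_controls=n_controls,
                                           or_magnitude=odds_ratio)
    summary.to_csv(out, sep="\t", index=False, float_format="%.10g")
    logger.info("wrote %s", out)


@main.command("calibrate")
@click.option("--design", default="trio", type=click.Choice(["trio", "cc"]))
@click.option("--n-replicates", default=500, show_default=True)
@click.option("--n-pools", default=5, show_default=True)
@click.option("--n-trios", default=500, show_default=True)
@click.option("--n-cases", default=500, show_default=True)
@click.option("--n-controls", default=500, show_default=True)
@click.option("--methods", default="ADABF", show_default=True,
              help="comma-separated subset of ADABF,ADABF1,ADA,TLC")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_calibrate(design, n_replicates, n_pools, n_trios, n_cases, n_controls,
                  methods, seed, out) -> None:
    """Type-I-error harness: null simulations and empirical rejection rates."""
    pools = [simpop.make_pool(seed=seed + 2000 + i) for i in range(n_pools)]
    config = simpop.SimConfig(design=design, n_trios=n_trios, n_cases=n_cases,
                              n_controls=n_controls, d=0)
    summary, _ = simpop.error_and_power_study(
        pools, config, n_replicates, methods=tuple(methods.split(",")), seed=seed)
    summary.to_csv(out, sep="\t", index=False, float_format="%.10g")
    logger.info("wrote %s", out)


if __name__ == "__main__":  # pragma: no cover
    main()
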