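"""Genotype, pedigree and phenotype I/O plus cohort-level quality control.

Genotypes are held as minor-allele dosages (0/1/2, NaN for missing) in a
:class:`GenotypeMatrix`; pedigrees as parent/offspring records in a
:class:`Pedigree` from which couple, full-sib and nuclear-family pair sets
are derived; phenotype/covariate tables as plain pandas DataFrames indexed
by individual id (``PhenoTable``).

On-disk formats are the field's standard ones: PLINK v1 binary
(.bed/.bim/.fam, SNP-major), 5-column whitespace pedigree text and
header-bearing TSV phenotype tables with ``NA`` for missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DegenerateTraitError,
    EmptyPanelError,
    FormatError,
)

__all__ = [
    "GenotypeMatrix",
    "Pedigree",
    "PhenoTable",
    "read_plink",
    "write_plink",
    "read_pedigree",
    "write_pedigree",
    "read_pheno",
    "write_pheno",
    "hwe_exact_pvalue",
    "qc_filter",
    "preprocess_trait",
]

#: Phenotype/covariate table: a DataFrame indexed by individual id with one
#: column per trait or covariate; missing values are NaN ("NA" on disk).
PhenoTable = pd.DataFrame

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01
# PLINK 2-bit codes -> dosage of the A1 allele: 00 hom A1, 01 missing,
# 10 het, 11 hom A2.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix with per-SNP metadata.

    Attributes
    ----------
    sample_ids
        Ordered individual identifiers (length n).
    snps
        Per-SNP metadata frame with columns ``snp_id``, ``chrom`` (1-22),
        ``pos``, ``a1`` (the counted, minor allele), ``a2``, ``freq``
        (minor-allele frequency in [0, 0.5], estimated from non-missing
        dosages).
    dosage
        ``(n, m)`` float array of minor-allele copies in {0, 1, 2}, NaN for
        missing.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    @classmethod
    def from_dosage(
        cls,
        dosage: np.ndarray,
        sample_ids: Sequence[str],
        snps: pd.DataFrame,
    ) -> "GenotypeMatrix":
        """Build a matrix, orienting every SNP to count its minor allele.

        SNPs whose counted-allele frequency exceeds 0.5 are flipped (dosage
        ``2 - x``, alleles swapped); exact ties at 0.5 keep the given
        orientation so that loading is deterministic.
        """
        dosage = np.asarray(dosage, dtype=float)
        snps = snps.reset_index(drop=True).copy()
        freq = _allele_freq(dosage)
        flip = freq > 0.5
        if flip.any():
            dosage = dosage.copy()
            dosage[:, flip] = 2.0 - dosage[:, flip]
            a1 = snps["a1"].to_numpy().copy()
            a2 = snps["a2"].to_numpy().copy()
            a1[flip], a2[flip] = snps["a2"].to_numpy()[flip], snps["a1"].to_numpy()[flip]
            snps["a1"], snps["a2"] = a1, a2
            freq = np.where(flip, 1.0 - freq, freq)
        snps["freq"] = freq
        return cls(list(sample_ids), snps, dosage)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def freq(self) -> np.ndarray:
        """Minor-allele frequency per SNP."""
        return self.snps["freq"].to_numpy()

    def validate(self) -> None:
        """Check the declared invariants, raising ConsistencyError on failure."""
        d = self.dosage
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ConsistencyError("dosages must be 0/1/2 or missing")
        chrom = self.snps["chrom"].to_numpy()
        if ((chrom < 1) | (chrom > 22)).any():
            raise ConsistencyError("only autosomes 1-22 are supported")
        recomputed = _allele_freq(d)
        if np.nanmax(np.abs(recomputed - self.freq), initial=0.0) > 1e-12:
            raise ConsistencyError("stored allele frequencies are stale")
        if (self.freq > 0.5 + 1e-12).any():
            raise ConsistencyError("allele frequencies must be minor (<= 0.5)")

    def subset(
        self,
        samples: np.ndarray | None = None,
        snps: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given boolean/index masks.

        Allele frequencies are re-estimated (and orientation re-derived) on
        the retained samples.
        """
        d = self.dosage
        ids = np.asarray(self.sample_ids, dtype=object)
        meta = self.snps
        if snps is not None:
            d = d[:, snps]
            sel = np.asarray(snps)
            meta = meta[sel] if sel.dtype == bool else meta.iloc[sel]
            meta = meta.reset_index(drop=True)
        if samples is not None:
            d = d[samples, :]
            ids = ids[samples]
        return GenotypeMatrix.from_dosage(d, list(ids), meta.drop(columns=["freq"], errors="ignore"))


def _allele_freq(dosage: np.ndarray) -> np.ndarray:
    """Counted-allele frequency per SNP from non-missing dosages."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        return np.nanmean(dosage, axis=0) / 2.0


@dataclass
class Pedigree:
    """Parent/offspring/sex/family records and the pair sets derived from them.

    ``records`` has columns ``iid``, ``father``, ``mother`` (empty string for
    unknown), ``sex`` (1 male, 2 female, 0 unknown) and ``family``.  Pair
    sets only reference individuals present in ``records``; parents named in
    a record but absent from the table do not generate pairs (they are
    outside the dataset).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.records.reset_index(drop=True)
        for col in ("father", "mother"):
            r[col] = r[col].fillna("").replace("0", "").astype(str)
        r["iid"] = r["iid"].astype(str)
        if r["iid"].duplicated().any():
            raise ConsistencyError("duplicate individual ids in pedigree")
        self.records = r
        self._check_acyclic()

    # -- derived structure ------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return list(self.records["iid"])

    def _check_acyclic(self) -> None:
        parent = {
            row.iid: tuple(p for p in (row.father, row.mother) if p)
            for row in self.records.itertuples()
        }
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            stack = [(node, iter(parent.get(node, ())))]
            state[node] = 1
            while stack:
                cur, it = stack[-1]
                for nxt in it:
                    if nxt not in parent:
                        continue
                    s = state.get(nxt)
                    if s == 1:
                        raise ConsistencyError(f"pedigree cycle through {nxt!r}")
                    if s is None:
                        state[nxt] = 1
                        stack.append((nxt, iter(parent.get(nxt, ()))))
                        break
                else:
                    state[cur] = 2
                    stack.pop()

        for iid in parent:
            if iid not in state:
                visit(iid)

    def parent_offspring_pairs(self) -> set[tuple[str, str]]:
        """Unordered (parent, child) pairs with both members in the dataset."""
        present = set(self.ids)
        pairs = set()
        for row in self.records.itertuples():
            for p in (row.father, row.mother):
                if p and p in present:
                    pairs.add(_pair(p, row.iid))
        return pairs

    def full_sib_pairs(self) -> set[tuple[str, str]]:
        """Pairs sharing both a known father and a known mother."""
        pairs = set()
        r = self.records
        both = r[(r["father"] != "") & (r["mother"] != "")]
        for (_, _), grp in both.groupby(["father", "mother"]):
            sibs = sorted(grp["iid"])
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    pairs.add(_pair(sibs[i], sibs[j]))
        return pairs

    def couple_pairs(self) -> set[tuple[str, str]]:
        """Pairs of individuals with at least one offspring in the dataset."""
        present = set(self.ids)
        pairs = set()
        for row in self.records.itertuples():
            if row.father and row.mother and row.father in present and row.mother in present:
                pairs.add(_pair(row.father, row.mother))
        return pairs

    def nuclear_family_pairs(self) -> set[tuple[str, str]]:
        """Union of parent-offspring, full-sib and couple pairs."""
        return self.parent_offspring_pairs() | self.full_sib_pairs() | self.couple_pairs()


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# PLINK binary I/O
# ---------------------------------------------------------------------------


def read_plink(prefix_or_bed: str | Path,
               bim_path: str | Path | None = None,
               fam_path: str | Path | None = None,
               ) -> tuple[GenotypeMatrix, Pedigree]:
    """Read a PLINK v1 binary fileset into a GenotypeMatrix and a Pedigree stub.

    Parameters may be a shared prefix or explicit .bed/.bim/.fam paths.
    Dosages are decoded from the 2-bit SNP-major encoding and re-oriented so
    that every SNP counts its minor allele (sample frequency <= 0.5; exact
    ties keep the file's A1).  The .fam parental columns populate the
    Pedigree stub, with the PLINK family id used as the family label.
    """
    prefix = Path(prefix_or_bed)
    if bim_path is None and fam_path is None and prefix.suffix == ".bed":
        prefix = prefix.with_suffix("")
    bed = prefix.with_suffix(".bed") if bim_path is None else Path(prefix_or_bed)
    bim = prefix.with_suffix(".bim") if bim_path is None else Path(bim_path)
    fam = prefix.with_suffix(".fam") if fam_path is None else Path(fam_path)
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)

    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["family", "iid", "father", "mother", "sex", "pheno"],
        dtype={"family": str, "iid": str, "father": str, "mother": str},
    )
    n, m = len(fam_df), len(bim_df)

    raw = Path(bed).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed}: not a PLINK v1 .bed file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        raise FormatError(f"{bed}: only SNP-major .bed files are supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise ConsistencyError(
            f"{bed}: expected {m * bytes_per_snp} data bytes for "
            f"{n} samples x {m} SNPs, found {body.size}"
        )
    codes = _unpack_codes(body.reshape(m, bytes_per_snp), n)  # (m, n)
    dosage = _CODE_TO_DOSAGE[codes].T  # (n, m)

    meta = bim_df[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    geno = GenotypeMatrix.from_dosage(dosage, list(fam_df["iid"]), meta)
    ped = Pedigree(fam_df[["iid", "father", "mother", "sex", "family"]].copy())
    return geno, ped


def _unpack_codes(rows: np.ndarray, n: int) -> np.ndarray:
    """(m, bytes) uint8 -> (m, n) 2-bit codes, first sample in the low bits."""
    out = np.empty((rows.shape[0], rows.shape[1] * 4), dtype=np.uint8)
    for k in range(4):
        out[:, k::4] = (rows >> (2 * k)) & 0b11
    return out[:, :n]


def write_plink(geno: GenotypeMatrix, prefix: str | Path,
                pedigree: Pedigree | None = None) -> None:
    """Write a GenotypeMatrix (and optional Pedigree) as PLINK v1 binary."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.n_samples, geno.n_snps

    code = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    d = geno.dosage.T
    code[d == 2.0] = 0b00
    code[d == 1.0] = 0b10
    code[d == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.concatenate(
            [code, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    packed = np.zeros((m, code.shape[1] // 4), dtype=np.uint8)
    for k in range(4):
        packed |= code[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())

    bim = geno.snps
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in bim.itertuples():
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{getattr(row, 'pos', 0)}"
                     f"\t{row.a1}\t{row.a2}\n")

    if pedigree is not None:
        rec = pedigree.records.set_index("iid").reindex(geno.sample_ids)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, iid in enumerate(geno.sample_ids):
            if pedigree is not None and iid in pedigree.records["iid"].values:
                r = rec.loc[iid]
                fam, fa, mo = r["family"], r["father"] or "0", r["mother"] or "0"
                sex = int(r["sex"]) if not pd.isna(r["sex"]) else 0
            else:
                fam, fa, mo, sex = iid, "0", "0", 0
            fh.write(f"{fam}\t{iid}\t{fa}\t{mo}\t{sex}\t-9\n")


# ---------------------------------------------------------------------------
# pedigree / phenotype text I/O
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> Pedigree:
    """Read 5-column whitespace pedigree text: id father mother sex family."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["iid", "father", "mother", "sex", "family"],
        dtype={"iid": str, "father": str, "mother": str, "family": str},
    )
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    r = ped.records
    with open(path, "w") as fh:
        for row in r.itertuples():
            fh.write(f"{row.iid}\t{row.father or '0'}\t{row.mother or '0'}"
                     f"\t{int(row.sex)}\t{row.family}\n")


def read_pheno(path: str | Path) -> PhenoTable:
    """Read a header-bearing TSV phenotype/covariate table ('NA' = missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"iid": str})
    if "iid" not in df.columns:
        raise FormatError(f"{path}: phenotype table needs an 'iid' column")
    if df["iid"].duplicated().any():
        raise ConsistencyError(f"{path}: duplicate individual ids")
    return df.set_index("iid")


def write_pheno(table: PhenoTable, path: str | Path) -> None:
    table.reset_index().rename(columns={"index": "iid"}).to_csv(
        path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def hwe_exact_pvalue(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg test p-value (Wigginton/PLINK flavour).

    Sums the probabilities, conditional on the allele counts, of all
    heterozygote counts whose probability does not exceed that of the
    observed count.
    """
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * n_hom_rare + n_het
    if rare > n:  # orient to the rarer allele
        rare = 2 * n - rare
    # heterozygote counts share the parity of the rare-allele count
    het_probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    het_probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((r-h+2)/2 * (c-h+2)/2) ...
    h = mid
    while h > 1:
        hom_r = (rare - h) // 2
        hom_c = n - h - (rare - h) // 2
        het_probs[h - 2] = het_probs[h] * h * (h - 1.0) / (
            4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        h -= 2
    h = mid
    while h <= rare - 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - (rare - h) // 2
        het_probs[h + 2] = het_probs[h] * 4.0 * hom_r * hom_c / (
            (h + 2.0) * (h + 1.0))
        h += 2
    het_probs /= het_probs.sum()
    obs = min(n_het, rare)
    p = het_probs[het_probs <= het_probs[obs] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_pvalues(dosage: np.ndarray) -> np.ndarray:
    n2 = np.nansum(dosage == 2.0, axis=0)
    n1 = np.nansum(dosage == 1.0, axis=0)
    n0 = np.nansum(dosage == 0.0, axis=0)
    return np.array([hwe_exact_pvalue(int(h), int(r), int(c))
                     for h, r, c in zip(n1, n2, n0)])


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-6,
    snp_miss_max: float = 0.02,
    ind_miss_max: float = 0.05,
    hwe_sample_mask: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply marker- then individual-level QC, returning a filtered copy.

    SNPs with minor-allele frequency below ``maf_min``, exact-HWE p-value
    below ``hwe_alpha`` or missingness above ``snp_miss_max`` are removed
    first; individuals with missingness above ``ind_miss_max`` (over the
    retained SNPs) are removed afterwards.  Returns the filtered matrix and
    a per-criterion count of removals.

    ``hwe_sample_mask`` restricts the Hardy-Weinberg test to a boolean
    subset of individuals (e.g. pedigree founders, so family structure does
    not masquerade as disequilibrium); by default all samples are tested.
    """
    for name, v in [("maf_min", maf_min), ("hwe_alpha", hwe_alpha),
                    ("snp_miss_max", snp_miss_max), ("ind_miss_max", ind_miss_max)]:
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {v}")

    d = geno.dosage
    report: dict[str, int] = {}

    keep = geno.freq >= maf_min
    report["snp_maf"] = int((~keep).sum())

    d_hwe = d if hwe_sample_mask is None else d[np.asarray(hwe_sample_mask)]
    hwe_p = np.ones(geno.n_snps)
    hwe_p[keep] = _hwe_pvalues(d_hwe[:, keep])
    drop_hwe = keep & (hwe_p < hwe_alpha)
    report["snp_hwe"] = int(drop_hwe.sum())
    keep &= ~drop_hwe

    miss = np.isnan(d).mean(axis=0)
    drop_miss = keep & (miss > snp_miss_max)
    report["snp_missing"] = int(drop_miss.sum())
    keep &= ~drop_miss

    if not keep.any():
        raise EmptyPanelError("all SNPs removed by QC")

    ind_miss = np.isnan(d[:, keep]).mean(axis=1)
    keep_ind = ind_miss <= ind_miss_max
    report["ind_missing"] = int((~keep_ind).sum())
    if not keep_ind.any():
        raise EmptyPanelError("all individuals removed by QC")

    return geno.subset(samples=keep_ind, snps=keep), report


# ---------------------------------------------------------------------------
# trait preprocessing
# ---------------------------------------------------------------------------


def preprocess_trait(
    pheno: PhenoTable,
    trait: str,
    transform: str = "identity",
    sd_limit: float = 4.0,
) -> tuple[PhenoTable, int]:
    """Transform a trait and mask outliers beyond ``sd_limit`` adjusted SDs.

    An optional natural-log transform is applied first; the trait is then
    adjusted by least squares for sex, age and age^2, and records whose
    adjusted residual lies outside mean +/- ``sd_limit`` SD are set to
    missing.  Returns a new table and the number of values masked.
    """
    if transform not in ("identity", "log"):
        raise ValueError(f"unknown transform {transform!r}")
    out = pheno.copy()
    y = out[trait].astype(float)
    if transform == "log":
        if (y.dropna() <= 0).any():
            raise DegenerateTraitError(
                f"trait {trait!r}: log transform requested on non-positive values")
        y = np.log(y)
        out[trait] = y

    covars = pd.DataFrame(index=out.index)
    covars["sex"] = out["sex"].astype(float)
    covars["age"] = out["age"].astype(float)
    covars["age2"] = covars["age"] ** 2
    obs = y.notna() & covars.notna().all(axis=1)
    if obs.sum() < 5:
        raise DegenerateTraitError(f"trait {trait!r}: too few complete records")
    X = np.column_stack([np.ones(obs.sum()), covars.loc[obs].to_numpy()])
    yv = y[obs].to_numpy()
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    sd = resid.std(ddof=X.shape[1])
    if sd <= 1e-10 * max(1.0, float(np.abs(yv).mean())):
        raise DegenerateTraitError(f"trait {trait!r}: zero residual variance")
    mask = np.abs(resid - resid.mean()) > sd_limit * sd
    idx = out.index[obs][mask]
    out.loc[idx, trait] = np.nan
    return out, int(mask.sum())
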