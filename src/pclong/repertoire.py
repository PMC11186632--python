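"""BCR heavy-chain repertoire statistics for plasma-cell subsets.

Clones are defined by the heavy-chain V gene (allele suffix stripped) plus
the exact CDR3 amino-acid sequence. The module builds clone tables from
AIRR-style rearrangement rows (dropping small clones of size < 10 by
default), estimates richness with Chao1, measures clonal overlap between
samples, detects "public" clones (shared by at least two samples from
different mice), scores enrichment of the most abundant public clones in a
target subset, summarizes isotype composition, and aggregates somatic
hypermutation (SHM) per IGHV allele with paired t tests across
allele-matched samples and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CloneRecord",
    "RepertoireSample",
    "PublicCloneCatalog",
    "build_clones",
    "chao1",
    "overlap_fraction",
    "find_public_clones",
    "top_public_enrichment",
    "isotype_composition",
    "shm_per_allele",
    "paired_allele_t",
    "paired_allele_tests",
]

DEFAULT_MIN_CLONE_SIZE = 10

_ISOTYPE_MAP = {
    "IGHM": "IgM", "IGHD": "IgD", "IGHG": "IgG", "IGHE": "IgE", "IGHA": "IgA",
}


def _strip_allele(v_call: str) -> str:
    """``IGHV8-9*01`` -> ``IGHV8-9`` (first call if multiple, comma-separated)."""
    first = str(v_call).split(",")[0].strip()
    return first.split("*")[0]


def _isotype_of(c_call) -> str:
    if c_call is None or (isinstance(c_call, float) and np.isnan(c_call)):
        return "unknown"
    s = str(c_call).upper()
    m = re.match(r"(IGH[MDGEA])", s)
    return _ISOTYPE_MAP[m.group(1)] if m else "unknown"


@dataclass
class CloneRecord:
    """One clone: unique (V gene, CDR3 aa) key within a sample.

    Member-level arrays (one entry per constituent sequence) retain each
    sequence's full V allele, V-region mutation count and V length so that
    SHM aggregation can draw one representative sequence per clone.
    """

    v_gene: str
    cdr3_aa: str
    v_allele: str
    isotype: str
    size: int
    mutation_count: int
    v_length: int
    sequence_ids: list[str] = field(default_factory=list)
    member_alleles: list[str] = field(default_factory=list)
    member_mutations: list[int] = field(default_factory=list)
    member_v_lengths: list[int] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str]:
        return (self.v_gene, self.cdr3_aa)


@dataclass
class RepertoireSample:
    """A sample's clones plus the metadata the comparisons group on."""

    sample_id: str
    mouse_id: str
    clones: list[CloneRecord]
    tissue: str | None = None
    subset: str | None = None
    timepoint: float | None = None
    age_group: str | None = None
    dropped_rows: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [c.key for c in self.clones]
        if len(keys) != len(set(keys)):
            raise ValueError(f"sample {self.sample_id}: duplicate clone keys")

    @property
    def keys(self) -> set[tuple[str, str]]:
        return {c.key for c in self.clones}

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray([c.size for c in self.clones], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "v_gene": [c.v_gene for c in self.clones],
                "junction_aa": [c.cdr3_aa for c in self.clones],
                "v_allele": [c.v_allele for c in self.clones],
                "isotype": [c.isotype for c in self.clones],
                "size": [c.size for c in self.clones],
                "mutation_count": [c.mutation_count for c in self.clones],
                "v_length": [c.v_length for c in self.clones],
            }
        )


def build_clones(
    rearrangements: pd.DataFrame,
    sample_id: str,
    mouse_id: str,
    min_size: int = DEFAULT_MIN_CLONE_SIZE,
    locus: str = "IGH",
    **metadata,
) -> RepertoireSample:
    """Group rearrangement rows into clones and drop small clones.

    Rows are grouped by (V gene without allele suffix, exact CDR3 amino-acid
    sequence) within the requested locus; clone size sums ``duplicate_count``.
    Clones below ``min_size`` (default 10) are removed. Rows missing a CDR3
    or carrying another locus are dropped and counted in
    ``RepertoireSample.dropped_rows``. The clone's representative isotype is
    the duplicate-count-weighted mode of member constant calls; its modal V
    allele is recorded alongside per-member alleles.
    """
    df = rearrangements.copy()
    for col in ("v_call", "junction_aa", "duplicate_count"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    dropped = {"missing_cdr3": 0, "other_locus": 0}
    bad_cdr3 = df["junction_aa"].isna() | (df["junction_aa"].astype(str).str.len() == 0)
    dropped["missing_cdr3"] = int(bad_cdr3.sum())
    df = df[~bad_cdr3]
    if "locus" in df.columns:
        other = df["locus"] != locus
        dropped["other_locus"] = int(other.sum())
        df = df[~other]
    if "sequence_id" not in df.columns:
        df = df.assign(sequence_id=[f"seq{i}" for i in range(len(df))])

    clones: list[CloneRecord] = []
    if len(df):
        df = df.assign(_v_gene=df["v_call"].map(_strip_allele))
        for (v_gene, cdr3), grp in df.groupby(["_v_gene", "junction_aa"], sort=True):
            size = int(grp["duplicate_count"].sum())
            iso_weight: dict[str, int] = {}
            for c_call, dup in zip(grp.get("c_call", pd.Series(dtype=object)),
                                   grp["duplicate_count"]):
                iso = _isotype_of(c_call)
                iso_weight[iso] = iso_weight.get(iso, 0) + int(dup)
            isotype = max(sorted(iso_weight), key=iso_weight.get) if iso_weight else "unknown"
            alleles = [str(a).split(",")[0].strip() for a in grp["v_call"]]
            muts = [int(m) for m in grp.get("mutation_count", pd.Series([0] * len(grp)))]
            vlens = [int(v) for v in grp.get("v_sequence_length", pd.Series([0] * len(grp)))]
            order = np.argsort(grp["sequence_id"].astype(str).to_numpy())
            clones.append(
                CloneRecord(
                    v_gene=str(v_gene),
                    cdr3_aa=str(cdr3),
                    v_allele=alleles[order[0]],
                    isotype=isotype,
                    size=size,
                    mutation_count=muts[order[0]],
                    v_length=vlens[order[0]],
                    sequence_ids=[grp["sequence_id"].astype(str).to_numpy()[i] for i in order],
                    member_alleles=[alleles[i] for i in order],
                    member_mutations=[muts[i] for i in order],
                    member_v_lengths=[vlens[i] for i in order],
                )
            )
    clones = [c for c in clones if c.size >= min_size]
    return RepertoireSample(
        sample_id=sample_id,
        mouse_id=mouse_id,
        clones=clones,
        dropped_rows=dropped,
        **metadata,
    )


def chao1(sample: RepertoireSample) -> float:
    """Chao1 richness from singleton (f1) and doubleton (f2) clone counts.

    ``S_obs + f1^2 / (2 f2)`` when doubletons exist; the bias-corrected form
    ``S_obs + f1 (f1 - 1) / 2`` when ``f2 = 0``. On size-filtered clone
    tables (no singletons) this reduces to observed richness.
    """
    sizes = sample.sizes
    if sizes.size == 0:
        raise ValueError(f"sample {sample.sample_id}: empty; Chao1 undefined")
    s_obs = sizes.size
    f1 = int((sizes == 1).sum())
    f2 = int((sizes == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / 2


def overlap_fraction(
    a: RepertoireSample, b: RepertoireSample, mode: str = "jaccard"
) -> float:
    """Percentage of clone keys shared between two samples.

    Modes: ``jaccard`` (shared / union, default), ``relative_to_first``
    (shared / |a|), ``relative_to_min`` (shared / smaller repertoire).
    """
    ka, kb = a.keys, b.keys
    if not ka or not kb:
        raise ValueError("overlap undefined for an empty sample")
    shared = len(ka & kb)
    if mode == "jaccard":
        denom = len(ka | kb)
    elif mode == "relative_to_first":
        denom = len(ka)
    elif mode == "relative_to_min":
        denom = min(len(ka), len(kb))
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    return 100.0 * shared / denom


@dataclass
class PublicCloneCatalog:
    """Clone keys found in >=2 samples from >=2 distinct mice."""

    occurrences: dict[tuple[str, str], list[tuple[str, str, str | None]]]
    total_abundance: dict[tuple[str, str], int]

    @property
    def keys(self) -> set[tuple[str, str]]:
        return set(self.occurrences)

    def __len__(self) -> int:
        return len(self.occurrences)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.occurrences):
            occ = self.occurrences[key]
            rows.append(
                {
                    "v_gene": key[0],
                    "junction_aa": key[1],
                    "n_samples": len(occ),
                    "n_mice": len({m for _, m, _ in occ}),
                    "total_abundance": self.total_abundance[key],
                    "samples": ";".join(s for s, _, _ in occ),
                }
            )
        return pd.DataFrame(rows)


def find_public_clones(samples) -> PublicCloneCatalog:
    """Catalog clone keys appearing in >=2 samples belonging to >=2 mice."""
    occ: dict[tuple[str, str], list[tuple[str, str, str | None]]] = {}
    tot: dict[tuple[str, str], int] = {}
    for s in samples:
        if not s.mouse_id:
            raise ValueError(f"sample {s.sample_id}: mouse_id required for public-clone logic")
        for c in s.clones:
            occ.setdefault(c.key, []).append((s.sample_id, s.mouse_id, s.subset))
            tot[c.key] = tot.get(c.key, 0) + c.size
    public = {
        k: v
        for k, v in occ.items()
        if len(v) >= 2 and len({m for _, m, _ in v}) >= 2
    }
    return PublicCloneCatalog(
        occurrences=public,
        total_abundance={k: tot[k] for k in public},
    )


def top_public_enrichment(
    catalog: PublicCloneCatalog,
    samples,
    n_top: int = 100,
    target_subset: str = "llpc",
) -> dict:
    """Enrichment of the most abundant public clones in a target subset.

    Ranks public clones by total abundance (ties broken by lexicographic
    clone key), takes the top ``n_top``, and reports the fraction present in
    at least one sample of ``target_subset``, alongside the baseline
    fraction of *all* observed clones present in target-subset samples.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if len(catalog) == 0:
        raise ValueError("empty public-clone catalog")
    ranked = sorted(
        catalog.keys, key=lambda k: (-catalog.total_abundance[k], k)
    )[:n_top]
    target_keys: set[tuple[str, str]] = set()
    all_keys: set[tuple[str, str]] = set()
    for s in samples:
        all_keys |= s.keys
        if s.subset == target_subset:
            target_keys |= s.keys
    top_frac = sum(k in target_keys for k in ranked) / len(ranked)
    baseline = (
        sum(k in target_keys for k in all_keys) / len(all_keys) if all_keys else 0.0
    )
    return {
        "n_top": len(ranked),
        "top_fraction_in_target": top_frac,
        "baseline_fraction_in_target": baseline,
        "target_subset": target_subset,
        "n_all_clones": len(all_keys),
    }


def isotype_composition(
    sample: RepertoireSample, weight: str = "clones"
) -> dict[str, float]:
    """Isotype fractions (simplex) of a sample, clone- or read-weighted."""
    if not sample.clones:
        raise ValueError(f"sample {sample.sample_id}: empty")
    if weight not in ("clones", "reads"):
        raise ValueError(f"unknown weight {weight!r}")
    acc: dict[str, float] = {}
    for c in sample.clones:
        w = 1.0 if weight == "clones" else float(c.size)
        acc[c.isotype] = acc.get(c.isotype, 0.0) + w
    total = sum(acc.values())
    return {iso: v / total for iso, v in sorted(acc.items())}


def shm_per_allele(sample: RepertoireSample, seed: int | None = None) -> dict[str, float]:
    """Mean SHM frequency per IGHV allele from one random sequence per clone.

    To avoid double-counting mutations within a clone, one member sequence is
    drawn uniformly per clone (seeded); its frequency is mutation count
    divided by V-gene length, and frequencies are averaged over the clones
    whose representative carries each allele.
    """
    rng = np.random.default_rng(seed)
    freq_by_allele: dict[str, list[float]] = {}
    for c in sorted(sample.clones, key=lambda c: c.key):
        n_members = max(len(c.member_mutations), 1)
        pick = int(rng.integers(n_members)) if n_members > 1 else 0
        if c.member_mutations:
            mut = c.member_mutations[pick]
            vlen = c.member_v_lengths[pick]
            allele = c.member_alleles[pick]
        else:
            mut, vlen, allele = c.mutation_count, c.v_length, c.v_allele
        if vlen <= 0:
            raise ValueError(f"clone {c.key}: V length must be positive")
        freq_by_allele.setdefault(allele, []).append(mut / vlen)
    return {a: float(np.mean(v)) for a, v in sorted(freq_by_allele.items())}


def paired_allele_t(a: dict[str, float], b: dict[str, float]) -> dict:
    """Paired t test on allele-matched SHM frequencies.

    Alleles absent from either table are not used. Fewer than two matched
    alleles skips the comparison; a nonzero constant difference (zero
    variance) is flagged degenerate with no p-value, while identical tables
    give t = 0, p = 1.
    """
    matched = sorted(set(a) & set(b))
    out = {"n_matched": len(matched), "alleles": matched, "status": "ok",
           "t": np.nan, "df": np.nan, "p": np.nan}
    if len(matched) < 2:
        out["status"] = "skipped_too_few_alleles"
        return out
    xa = np.asarray([a[m] for m in matched])
    xb = np.asarray([b[m] for m in matched])
    diff = xa - xb
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            out.update(t=0.0, df=len(matched) - 1, p=1.0)
        else:
            out["status"] = "degenerate_zero_variance"
        return out
    t_stat, p = sps.ttest_rel(xa, xb)
    out.update(t=float(t_stat), df=len(matched) - 1, p=float(p))
    return out


def paired_allele_tests(comparisons: dict[str, tuple[dict, dict]]) -> pd.DataFrame:
    """Family of paired allele tests with Benjamini-Hochberg correction.

    ``comparisons`` maps a comparison name to a pair of per-allele SHM
    tables. BH adjustment is applied across the comparisons that yielded a
    p-value; skipped/degenerate comparisons are reported with NaN.
    """
    rows = []
    for name, (a, b) in comparisons.items():
        res = paired_allele_t(a, b)
        rows.append({"comparison": name, **{k: res[k] for k in
                                            ("n_matched", "t", "df", "p", "status")}})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    valid = df["p"].notna()
    if valid.any():
        df.loc[valid, "p_adj"] = multipletests(
            df.loc[valid, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return df
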