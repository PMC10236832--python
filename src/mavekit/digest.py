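"""Per-sample FASTQ digestion into a variant count table.

One sequencing library at a time, reads are pushed through a fixed cascade
of filters and transformations:

1. adapter detection (exact substring) — contaminated read (pairs) dropped;
2. segmentation under the read layout (including primer anchoring);
3. optional reverse-complementing of extracted components;
4. optional merging of the forward and reverse variable regions;
5. average-quality and N-content filters on the variable/UMI sequences;
6. nearest-wild-type matching (Hamming) with mutation-budget,
   mutation-quality and forbidden-codon checks;
7. constant-region check against reference(s), feeding the per-quality
   sequencing-error tally;
8. accumulation of (variant name, UMI) into the count table.

A read (pair) is claimed by the first step at which it fails; the filter
tally therefore partitions the input exactly.  The result bundles the count
table, the ordered filter tally, the per-quality error tally and a record
of all parameters.
"""

from __future__ import annotations

import datetime
import itertools
import json
from collections import Counter
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .collapse import CollapseParams, collapse_sequences, collapse_umis
from .experiment import classify_mutations
from .layout import (
    NO_PRIMER,
    READ_LENGTH_MISMATCH,
    ComponentSet,
    ElementSpec,
    segment_read,
)

__version__ = "0.1.0"

# ---------------------------------------------------------------- constants

F_ADAPTER = "fAdapter"
F_NO_PRIMER = "fNoPrimer"
F_READ_LENGTH = "fReadLengthMismatch"
F_MERGE_FAILED = "fMergeFailed"
F_AVG_QUAL = "fAvgQualTooLow"
F_N_VAR = "fTooManyNinVar"
F_N_UMI = "fTooManyNinUmi"
F_NO_WILDTYPE = "fNoValidWildtype"
F_TOO_MANY_MUT = "fTooManyMutations"
F_MUT_QUAL = "fMutQualTooLow"
F_FORBIDDEN_CODON = "fForbiddenCodon"
F_CONSTANT = "fConstantMismatch"

#: filter reasons in cascade order
FILTER_REASONS = (
    F_ADAPTER,
    F_NO_PRIMER,
    F_READ_LENGTH,
    F_MERGE_FAILED,
    F_AVG_QUAL,
    F_N_VAR,
    F_N_UMI,
    F_NO_WILDTYPE,
    F_TOO_MANY_MUT,
    F_MUT_QUAL,
    F_FORBIDDEN_CODON,
    F_CONSTANT,
)

_SEGMENT_REASON = {NO_PRIMER: F_NO_PRIMER, READ_LENGTH_MISMATCH: F_READ_LENGTH}

MERGE_FAILED = "mergeFailed"

MAX_PHRED = 93

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def phred_from_string(qual: str) -> np.ndarray:
    """Phred scores from a Phred+33 encoded quality string."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33


def iupac_codon_match(codon: str, pattern: str) -> bool:
    """True when every base of `codon` is allowed by the degenerate
    `pattern` (e.g. pattern ``"NNW"`` matches any codon ending in A or T)."""
    if len(codon) != len(pattern):
        return False
    return all(b in IUPAC.get(p, "") for b, p in zip(codon, pattern.upper()))


# ------------------------------------------------------------------ tallies


@dataclass
class FilterTally:
    """Ordered per-reason read counters; ``n_total`` always equals
    ``n_retained`` plus the sum of all filter counters."""

    n_total: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in FILTER_REASONS}
    )
    n_retained: int = 0

    def add(self, reason: str) -> None:
        self.counts[reason] += 1

    @property
    def n_filtered(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict[str, int]:
        d = {"nTotal": self.n_total}
        d.update(self.counts)
        d["nRetained"] = self.n_retained
        return d

    def __iadd__(self, other: "FilterTally") -> "FilterTally":
        self.n_total += other.n_total
        self.n_retained += other.n_retained
        for r in FILTER_REASONS:
            self.counts[r] += other.counts[r]
        return self


@dataclass
class ErrorTally:
    """Per-base-quality match/mismatch counts against the constant-region
    reference, the raw material for sequencing-error-rate estimation."""

    n_match: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_PHRED + 1, dtype=np.int64)
    )
    n_mismatch: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_PHRED + 1, dtype=np.int64)
    )

    def accumulate(self, match: np.ndarray, mismatch: np.ndarray) -> None:
        self.n_match += match
        self.n_mismatch += mismatch

    @property
    def total_bases(self) -> int:
        return int(self.n_match.sum() + self.n_mismatch.sum())


def estimate_error_rates(tally: ErrorTally) -> pd.DataFrame:
    """Sequencing error rate stratified by base quality.

    rate(q) = nMismatch(q) / (nMatch(q) + nMismatch(q)); qualities never
    observed are omitted.
    """
    total = tally.n_match + tally.n_mismatch
    keep = total > 0
    q = np.nonzero(keep)[0]
    return pd.DataFrame(
        {
            "quality": q,
            "nTotal": total[keep],
            "nMismatch": tally.n_mismatch[keep],
            "rate": tally.n_mismatch[keep] / total[keep],
        }
    )


# --------------------------------------------------------------- parameters


@dataclass(frozen=True)
class MergeOptions:
    """Constraints on merging a read pair's variable regions.

    Overlaps are scanned from the longest allowed width down to
    `min_overlap`; the first overlap with mismatch fraction at most
    `max_mismatch_fraction` and a merged length inside
    [`min_merged_length`, `max_merged_length`] wins.  ``None`` bounds are
    unconstrained.
    """

    min_overlap: int = 1
    max_overlap: int | None = None
    min_merged_length: int | None = None
    max_merged_length: int | None = None
    max_mismatch_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_mismatch_fraction <= 1.0:
            raise ValueError("max_mismatch_fraction must be in [0, 1]")


@dataclass
class DigestParams:
    """All per-read thresholds and modes of the digestion cascade.

    `wildtypes` is the wild-type set used for single-end, merged, and the
    forward side of paired non-merged processing; `wildtypes_rev` the set
    for the reverse side in paired non-merged processing.  With no
    wild-types the run is in sequence (barcode) mode and variants are named
    by their observed sequence.
    """

    adapter_fwd: str | None = None
    adapter_rev: str | None = None
    merge: bool = False
    merge_options: MergeOptions = field(default_factory=MergeOptions)
    rev_complement_fwd: bool = False
    rev_complement_rev: bool = False
    wildtypes: dict[str, str] | None = None
    wildtypes_rev: dict[str, str] | None = None
    unit: str = "base"
    max_mutations: int | None = None
    min_mutation_quality: int = 0
    forbidden_codons: str | None = None
    avg_qual_min: float = 0.0
    max_n_variable: int | None = None
    max_n_umi: int | None = None
    constant_fwd: Sequence[str] | None = None
    constant_rev: Sequence[str] | None = None
    max_constant_mismatch: int | None = None
    max_n_reads: int | None = None
    excluded_path: str | None = None
    collapse: CollapseParams | None = None
    umi_collapse_max_dist: int = 0

    def __post_init__(self) -> None:
        if self.unit not in ("base", "codon"):
            raise ValueError("unit must be 'base' or 'codon'")
        for name in (
            "min_mutation_quality",
            "avg_qual_min",
            "umi_collapse_max_dist",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in (
            "max_mutations",
            "max_n_variable",
            "max_n_umi",
            "max_constant_mismatch",
            "max_n_reads",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.forbidden_codons is not None and len(self.forbidden_codons) != 3:
            raise ValueError("forbidden_codons must be a length-3 IUPAC string")
        if self.collapse is not None and (
            self.wildtypes or self.wildtypes_rev
        ):
            raise ValueError(
                "sequence collapsing applies only in reference-free mode"
            )

    def record(self) -> dict:
        """JSON-able parameter record (with timestamp and version added by
        :func:`digest_sample`)."""
        rec = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (MergeOptions, CollapseParams)):
                v = {g.name: getattr(v, g.name) for g in dc_fields(v)}
            elif isinstance(v, tuple):
                v = list(v)
            rec[f.name] = v
        return rec


# ----------------------------------------------------------- per-read steps


def contains_adapter(
    fwd_seq: str,
    rev_seq: str | None,
    adapter_fwd: str | None,
    adapter_rev: str | None,
) -> bool:
    """Exact-substring adapter detection on either mate."""
    if adapter_fwd and adapter_fwd in fwd_seq:
        return True
    if adapter_rev and rev_seq is not None and adapter_rev in rev_seq:
        return True
    return False


def merge_pair(
    fwd_seq: str,
    fwd_qual: np.ndarray,
    rev_seq: str,
    rev_qual: np.ndarray,
    options: MergeOptions = MergeOptions(),
) -> tuple[str, np.ndarray] | str:
    """Merge two variable regions over their best overlap.

    `rev_seq` must already be oriented like the forward sequence (i.e.
    reverse-complemented, with its qualities reversed).  Overlap widths are
    tried from the longest allowed down; the first valid one wins.  In the
    overlap, concordant positions keep the maximum quality; discordant
    positions keep the higher-quality base (tie → forward base).

    Returns (merged sequence, merged qualities) or ``"mergeFailed"``.
    """
    nf, nr = len(fwd_seq), len(rev_seq)
    hi = min(nf, nr)
    if options.max_overlap is not None:
        hi = min(hi, options.max_overlap)
    lo = options.min_overlap
    min_len = options.min_merged_length or 0
    max_len = (
        options.max_merged_length if options.max_merged_length is not None else np.inf
    )
    f = np.frombuffer(fwd_seq.encode("ascii"), dtype=np.uint8)
    r = np.frombuffer(rev_seq.encode("ascii"), dtype=np.uint8)
    for w in range(hi, lo - 1, -1):
        merged_len = nf + nr - w
        if not (min_len <= merged_len <= max_len):
            continue
        a, b = f[nf - w :], r[:w]
        qa, qb = fwd_qual[nf - w :], rev_qual[:w]
        diff = a != b
        if diff.sum() / w > options.max_mismatch_fraction:
            continue
        take_rev = diff & (qb > qa)
        cons = np.where(take_rev, b, a)
        cons_q = np.where(diff, np.where(take_rev, qb, qa), np.maximum(qa, qb))
        seq = fwd_seq[: nf - w] + cons.tobytes().decode("ascii") + rev_seq[w:]
        qual = np.concatenate([fwd_qual[: nf - w], cons_q, rev_qual[w:]])
        return seq, qual
    return MERGE_FAILED


def quality_filters(components: ComponentSet, params: DigestParams) -> str | None:
    """Average-quality and N-content filters (step 5), in reason order."""
    return _quality_filters(
        components.variable, components.variable_qual, components.umi, params
    )


def _quality_filters(
    var_seq: str, var_qual: np.ndarray, umi: str, params: DigestParams
) -> str | None:
    if len(var_qual) and float(var_qual.mean()) < params.avg_qual_min:
        return F_AVG_QUAL
    if params.max_n_variable is not None and var_seq.count("N") > params.max_n_variable:
        return F_N_VAR
    if params.max_n_umi is not None and umi.count("N") > params.max_n_umi:
        return F_N_UMI
    return None


@dataclass
class MatchResult:
    """Nearest-wild-type assignment for one variable region.

    `mutations` holds (1-based position, reference, observed) triples in
    base units or codon units according to the matching unit.
    """

    wt_name: str
    wt_seq: str
    mutations: list[tuple[int, str, str]]
    n_mut_bases: int
    n_mut_codons: int
    mut_base_positions: np.ndarray  # 0-based, internal


class WildtypeMatcher:
    """Pre-encoded wild-type set for repeated Hamming matching.

    Hamming comparison requires equal lengths; wild-types whose length
    differs from the query are not candidates.
    """

    def __init__(self, wildtypes: dict[str, str]):
        if not wildtypes:
            raise ValueError("wild-type set must be non-empty")
        self.wildtypes = dict(wildtypes)
        self._by_length: dict[int, tuple[list[str], np.ndarray]] = {}
        groups: dict[int, list[str]] = {}
        for name, seq in wildtypes.items():
            if not seq:
                raise ValueError(f"wild-type {name!r} has empty sequence")
            groups.setdefault(len(seq), []).append(name)
        for L, names in groups.items():
            mat = np.vstack(
                [
                    np.frombuffer(wildtypes[n].upper().encode("ascii"), dtype=np.uint8)
                    for n in names
                ]
            )
            self._by_length[L] = (names, mat)

    def nearest(self, var_seq: str) -> tuple[str, int, bool] | None:
        """(closest wild-type name, distance, tie?) or ``None`` when no
        wild-type has the query's length.  Ties report the lexicographically
        first name."""
        group = self._by_length.get(len(var_seq))
        if group is None:
            return None
        names, mat = group
        q = np.frombuffer(var_seq.encode("ascii"), dtype=np.uint8)
        dists = (mat != q).sum(axis=1)
        dmin = int(dists.min())
        idx = np.nonzero(dists == dmin)[0]
        best = min(names[i] for i in idx)
        return best, dmin, len(idx) > 1


def _match_stage_nearest(
    matcher: WildtypeMatcher,
    var_seq: str,
    unit: str,
    max_mutations: int | None,
) -> MatchResult | str:
    """Step-6 core: nearest wild-type within the base-space search budget.

    The budget is `max_mutations` bases in base units and
    ``3 * max_mutations`` bases in codon units (the most bases that many
    codons can span); the codon-count limit itself is a separate check.
    """
    hit = matcher.nearest(var_seq)
    if hit is None:
        return F_NO_WILDTYPE
    name, dist, tie = hit
    if max_mutations is not None:
        budget = max_mutations if unit == "base" else 3 * max_mutations
        if dist > budget:
            return F_NO_WILDTYPE
    if tie:
        return F_NO_WILDTYPE
    wt = matcher.wildtypes[name].upper()
    var = var_seq.upper()
    pos = np.array([i for i in range(len(var)) if var[i] != wt[i]], dtype=np.int64)
    codons = sorted({int(p) // 3 for p in pos})
    if unit == "codon":
        mutations = [
            (c + 1, wt[3 * c : 3 * c + 3], var[3 * c : 3 * c + 3]) for c in codons
        ]
    else:
        mutations = [(int(p) + 1, wt[p], var[p]) for p in pos]
    return MatchResult(name, wt, mutations, int(len(pos)), len(codons), pos)


def _check_mutation_budget(
    match: MatchResult, unit: str, max_mutations: int | None
) -> str | None:
    if unit == "codon" and max_mutations is not None:
        if match.n_mut_codons > max_mutations:
            return F_TOO_MANY_MUT
    return None


def _check_mutation_quality(
    match: MatchResult, var_qual: np.ndarray, min_quality: int
) -> str | None:
    if min_quality > 0 and len(match.mut_base_positions):
        if (var_qual[match.mut_base_positions] < min_quality).any():
            return F_MUT_QUAL
    return None


def _check_forbidden_codons(
    match: MatchResult, var_seq: str, pattern: str | None
) -> str | None:
    if pattern is None:
        return None
    var = var_seq.upper()
    for c in sorted({int(p) // 3 for p in match.mut_base_positions}):
        codon = var[3 * c : 3 * c + 3]
        if len(codon) == 3 and iupac_codon_match(codon, pattern):
            return F_FORBIDDEN_CODON
    return None


def match_to_wildtype(
    var_seq: str,
    var_qual: np.ndarray,
    wildtypes: dict[str, str],
    params: DigestParams,
) -> MatchResult | str:
    """Assign a variable region to its nearest wild-type (step 6).

    Returns a :class:`MatchResult` or a filter reason:
    ``fNoValidWildtype`` (no candidate within the budget, or a tie between
    wild-types), ``fTooManyMutations`` (codon unit, mutated-codon count over
    the limit), ``fMutQualTooLow`` (a mutated base below the quality
    threshold), ``fForbiddenCodon`` (a mutated codon matching the forbidden
    IUPAC pattern).
    """
    matcher = WildtypeMatcher(wildtypes)
    res = _match_stage_nearest(matcher, var_seq, params.unit, params.max_mutations)
    if isinstance(res, str):
        return res
    for reason in (
        _check_mutation_budget(res, params.unit, params.max_mutations),
        _check_mutation_quality(res, var_qual, params.min_mutation_quality),
        _check_forbidden_codons(res, var_seq, params.forbidden_codons),
    ):
        if reason is not None:
            return reason
    return res


def name_variant(match: MatchResult, unit: str) -> str:
    """Variant identifier: bare wild-type name for an exact match, else
    ``WT.pos.ALT`` terms (1-based base position + base, or codon index +
    codon) joined by ``_`` in position order."""
    if not match.mutations:
        return match.wt_name
    return "_".join(
        f"{match.wt_name}.{pos}.{alt}" for pos, _, alt in match.mutations
    )


def check_constant(
    const_seq: str,
    const_qual: np.ndarray,
    const_refs: Sequence[str],
    max_mismatch: int | None,
) -> tuple[bool, np.ndarray, np.ndarray]:
    """Constant-region check (step 7) and per-quality error tallies.

    The read's constant region is compared to the nearest reference by
    Hamming distance.  The check fails when the distance exceeds
    `max_mismatch` or when two references tie at the minimum; the
    per-quality match/mismatch tallies against the (first) nearest
    reference are returned either way.
    """
    cands = [r.upper() for r in const_refs if len(r) == len(const_seq)]
    match = np.zeros(MAX_PHRED + 1, dtype=np.int64)
    mismatch = np.zeros(MAX_PHRED + 1, dtype=np.int64)
    if not cands:
        return False, match, mismatch
    q = np.frombuffer(const_seq.upper().encode("ascii"), dtype=np.uint8)
    mat = np.vstack([np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in cands])
    dists = (mat != q).sum(axis=1)
    dmin = int(dists.min())
    tie = int((dists == dmin).sum()) > 1
    ref = mat[int(dists.argmin())]
    diff = ref != q
    quals = np.clip(const_qual, 0, MAX_PHRED)
    np.add.at(match, quals[~diff], 1)
    np.add.at(mismatch, quals[diff], 1)
    ok = not tie and (max_mismatch is None or dmin <= max_mismatch)
    return ok, match, mismatch


# ------------------------------------------------------------ count records


@dataclass
class VariantRecord:
    """One row of the per-sample count table."""

    name: str
    read_count: int = 0
    umi_count: int | None = None
    n_mut_bases: int | None = None
    n_mut_codons: int | None = None
    n_mut_aas: int | None = None
    mutation_types: frozenset[str] = frozenset()
    sequences: set[str] = field(default_factory=set)
    wildtype: str | None = None
    sequence: str | None = None
    wt_sequence: str | None = None
    umis: Counter | None = None  # transient, dropped after deduplication


@dataclass
class DigestResult:
    """Output of :func:`digest_sample`: count table, ordered filter tally,
    per-quality error tally and the parameter record."""

    count_table: dict[str, VariantRecord]
    filter_tally: FilterTally
    error_tally: ErrorTally
    params_record: dict

    # -------------------------------------------------------------- export
    def counts_frame(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.count_table):
            r = self.count_table[name]
            rows.append(
                {
                    "variant": name,
                    "readCount": r.read_count,
                    "umiCount": r.umi_count,
                    "nMutBases": r.n_mut_bases,
                    "nMutCodons": r.n_mut_codons,
                    "nMutAAs": r.n_mut_aas,
                    "mutationTypes": ",".join(sorted(r.mutation_types)),
                    "sequences": ",".join(sorted(r.sequences)),
                    "wildtype": r.wildtype,
                    "sequence": r.sequence,
                    "wtSequence": r.wt_sequence,
                }
            )
        cols = [
            "variant", "readCount", "umiCount", "nMutBases", "nMutCodons",
            "nMutAAs", "mutationTypes", "sequences", "wildtype", "sequence",
            "wtSequence",
        ]
        return pd.DataFrame(rows, columns=cols)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.counts_frame().to_csv(path / "counts.tsv", sep="\t", index=False)
        pd.Series(self.filter_tally.as_dict(), name="count").rename_axis(
            "reason"
        ).to_csv(path / "filters.tsv", sep="\t")
        q = np.arange(MAX_PHRED + 1)
        keep = (self.error_tally.n_match + self.error_tally.n_mismatch) > 0
        pd.DataFrame(
            {
                "quality": q[keep],
                "nMatch": self.error_tally.n_match[keep],
                "nMismatch": self.error_tally.n_mismatch[keep],
            }
        ).to_csv(path / "error_tally.tsv", sep="\t", index=False)
        estimate_error_rates(self.error_tally).to_csv(
            path / "error_rates.tsv", sep="\t", index=False
        )
        (path / "params.json").write_text(
            json.dumps(self.params_record, indent=2, sort_keys=True, default=str)
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "DigestResult":
        path = Path(path)
        df = pd.read_csv(
            path / "counts.tsv",
            sep="\t",
            dtype={
                "variant": str, "mutationTypes": str, "sequences": str,
                "wildtype": str, "sequence": str, "wtSequence": str,
            },
        )
        table: dict[str, VariantRecord] = {}
        for _, row in df.iterrows():
            def _i(v):
                return None if pd.isna(v) else int(v)

            types = row["mutationTypes"]
            table[row["variant"]] = VariantRecord(
                name=row["variant"],
                read_count=int(row["readCount"]),
                umi_count=_i(row["umiCount"]),
                n_mut_bases=_i(row["nMutBases"]),
                n_mut_codons=_i(row["nMutCodons"]),
                n_mut_aas=_i(row["nMutAAs"]),
                mutation_types=frozenset(
                    types.split(",") if isinstance(types, str) and types else []
                ),
                sequences=set(
                    row["sequences"].split(",")
                    if isinstance(row["sequences"], str) and row["sequences"]
                    else []
                ),
                wildtype=None if pd.isna(row["wildtype"]) else row["wildtype"],
                sequence=None if pd.isna(row["sequence"]) else row["sequence"],
                wt_sequence=None
                if pd.isna(row["wtSequence"])
                else row["wtSequence"],
            )
        fl = pd.read_csv(path / "filters.tsv", sep="\t", index_col="reason")["count"]
        tally = FilterTally(
            n_total=int(fl["nTotal"]),
            counts={r: int(fl[r]) for r in FILTER_REASONS},
            n_retained=int(fl["nRetained"]),
        )
        err = ErrorTally()
        et = pd.read_csv(path / "error_tally.tsv", sep="\t")
        for _, row in et.iterrows():
            err.n_match[int(row["quality"])] = int(row["nMatch"])
            err.n_mismatch[int(row["quality"])] = int(row["nMismatch"])
        params = json.loads((path / "params.json").read_text())
        return cls(table, tally, err, params)


# --------------------------------------------------------------- main entry


class _ExcludedWriter:
    """Writes filtered-out reads to FASTQ with the reason appended to the
    read identifier (``@ID reason``)."""

    def __init__(self, prefix: str, paired: bool):
        self.paired = paired
        if paired:
            self.f1 = open(f"{prefix}_R1.fastq", "w")
            self.f2 = open(f"{prefix}_R2.fastq", "w")
        else:
            self.f1 = open(f"{prefix}.fastq", "w")
            self.f2 = None

    @staticmethod
    def _write(fh, name, reason, seq, qual):
        fh.write(f"@{name} {reason}\n{seq}\n+\n{qual}\n")

    def write(self, reason, r1, r2=None):
        self._write(self.f1, r1.name, reason, r1.sequence, r1.quality)
        if self.f2 is not None and r2 is not None:
            self._write(self.f2, r2.name, reason, r2.sequence, r2.quality)

    def close(self):
        self.f1.close()
        if self.f2 is not None:
            self.f2.close()


def _as_list(x) -> list:
    if x is None:
        return []
    if isinstance(x, (str, Path)):
        return [x]
    return list(x)


def _read_pairs(fwd_paths, rev_paths, max_reads):
    """Yield (record, mate-or-None) across all file (pairs), capped at
    `max_reads`; raises on truncated/mismatched pairs."""
    n = 0
    for i, f1 in enumerate(fwd_paths):
        f2 = rev_paths[i] if rev_paths else None
        with pysam.FastxFile(str(f1)) as h1:
            h2 = pysam.FastxFile(str(f2)) if f2 else None
            try:
                it = (
                    itertools.zip_longest(h1, h2)
                    if h2 is not None
                    else ((r, None) for r in h1)
                )
                for r1, r2 in it:
                    if r1 is None or (h2 is not None and r2 is None):
                        raise ValueError(
                            f"paired FASTQ files {f1} / {f2} have unequal read "
                            f"counts (record {n})"
                        )
                    yield r1, r2
                    n += 1
                    if max_reads is not None and n >= max_reads:
                        return
            finally:
                if h2 is not None:
                    h2.close()


def digest_sample(
    fastq_fwd: str | Path | Sequence[str | Path],
    layout_fwd: ElementSpec,
    params: DigestParams,
    fastq_rev: str | Path | Sequence[str | Path] | None = None,
    layout_rev: ElementSpec | None = None,
) -> DigestResult:
    """Digest one sample's FASTQ file (pairs) into a variant count table.

    Multiple file (pairs) are internally concatenated.  The output is
    deterministic and independent of read order (UMI and sequence
    collapsing operate on abundance-sorted tables).
    """
    fwd_paths = _as_list(fastq_fwd)
    rev_paths = _as_list(fastq_rev)
    if not fwd_paths:
        raise ValueError("at least one forward FASTQ file is required")
    paired = bool(rev_paths)
    if paired and len(rev_paths) != len(fwd_paths):
        raise ValueError("unequal numbers of forward and reverse FASTQ files")
    if paired and layout_rev is None:
        raise ValueError("paired input requires a reverse read layout")
    if paired and not params.merge:
        if (params.wildtypes is None) != (params.wildtypes_rev is None):
            raise ValueError(
                "paired non-merged matching needs wild-type sets for both "
                "sides (or neither, for sequence mode)"
            )
    for p in fwd_paths + rev_paths:
        if not Path(p).exists():
            raise FileNotFoundError(str(p))

    matcher = WildtypeMatcher(params.wildtypes) if params.wildtypes else None
    matcher_rev = (
        WildtypeMatcher(params.wildtypes_rev) if params.wildtypes_rev else None
    )
    has_umi = "U" in layout_fwd.codes or (
        layout_rev is not None and paired and "U" in layout_rev.codes
    )

    tally = FilterTally()
    errors = ErrorTally()
    table: dict[str, VariantRecord] = {}
    writer = (
        _ExcludedWriter(params.excluded_path, paired)
        if params.excluded_path
        else None
    )

    try:
        for r1, r2 in _read_pairs(fwd_paths, rev_paths, params.max_n_reads):
            tally.n_total += 1
            out = _process_pair(
                r1, r2, layout_fwd, layout_rev, params, matcher, matcher_rev,
                errors,
            )
            if isinstance(out, str):
                tally.add(out)
                if writer is not None:
                    writer.write(out, r1, r2)
                continue
            tally.n_retained += 1
            name, umi, observed, ann = out
            rec = table.get(name)
            if rec is None:
                rec = VariantRecord(name=name, umis=Counter() if has_umi else None)
                rec.wildtype = ann.get("wildtype")
                rec.sequence = ann.get("sequence")
                rec.wt_sequence = ann.get("wt_sequence")
                rec.n_mut_bases = ann.get("n_mut_bases")
                rec.n_mut_codons = ann.get("n_mut_codons")
                rec.n_mut_aas = ann.get("n_mut_aas")
                rec.mutation_types = ann.get("mutation_types", frozenset())
                table[name] = rec
            rec.read_count += 1
            rec.sequences.add(observed)
            if rec.umis is not None:
                rec.umis[umi] += 1
    finally:
        if writer is not None:
            writer.close()

    # reference-free greedy collapsing of similar sequences
    if params.collapse is not None and table:
        counts = {name: rec.read_count for name, rec in table.items()}
        merged = collapse_sequences(counts, params.collapse)
        new_table: dict[str, VariantRecord] = {}
        for seed, (total, members) in merged.items():
            rec = table[seed]
            rec.read_count = total
            for m in members:
                if m == seed:
                    continue
                rec.sequences |= table[m].sequences
                if rec.umis is not None and table[m].umis is not None:
                    rec.umis += table[m].umis
            new_table[seed] = rec
        table = new_table

    # UMI deduplication within each variant
    for rec in table.values():
        if rec.umis is not None:
            rec.umi_count = collapse_umis(dict(rec.umis), params.umi_collapse_max_dist)
            rec.umis = None

    record = params.record()
    record["timestamp"] = datetime.datetime.now().isoformat(timespec="seconds")
    record["version"] = __version__
    record["fastq_fwd"] = [str(p) for p in fwd_paths]
    record["fastq_rev"] = [str(p) for p in rev_paths]
    return DigestResult(table, tally, errors, record)


def _process_pair(r1, r2, layout_fwd, layout_rev, params, matcher, matcher_rev,
                  errors: ErrorTally):
    """Apply the per-read cascade; returns a filter reason string or
    (variant name, umi, observed sequence, annotation dict)."""
    seq1 = r1.sequence.upper()
    seq2 = r2.sequence.upper() if r2 is not None else None

    # 1. adapters
    if contains_adapter(seq1, seq2, params.adapter_fwd, params.adapter_rev):
        return F_ADAPTER

    # 2. segmentation
    q1 = phred_from_string(r1.quality)
    comp1 = segment_read(seq1, q1, layout_fwd)
    if isinstance(comp1, str):
        return _SEGMENT_REASON[comp1]
    comp2 = None
    if r2 is not None:
        q2 = phred_from_string(r2.quality)
        comp2 = segment_read(seq2, q2, layout_rev)
        if isinstance(comp2, str):
            return _SEGMENT_REASON[comp2]

    # 3. optional reverse-complementing of extracted components
    if params.rev_complement_fwd:
        _revcomp_components(comp1)
    rev_oriented = False
    if comp2 is not None and params.rev_complement_rev:
        _revcomp_components(comp2)
        rev_oriented = True

    # 4. optional merging of the variable regions
    merged_mode = params.merge and comp2 is not None
    if merged_mode:
        rv, rq = comp2.variable, comp2.variable_qual
        if not rev_oriented:
            rv = reverse_complement(rv)
            rq = rq[::-1]
        m = merge_pair(comp1.variable, comp1.variable_qual, rv, rq,
                       params.merge_options)
        if isinstance(m, str):
            return F_MERGE_FAILED
        var_seq, var_qual = m
        sides = [(var_seq, var_qual, matcher)]
    elif comp2 is not None:
        var_seq = comp1.variable + comp2.variable
        var_qual = np.concatenate([comp1.variable_qual, comp2.variable_qual])
        sides = [
            (comp1.variable, comp1.variable_qual, matcher),
            (comp2.variable, comp2.variable_qual, matcher_rev),
        ]
    else:
        var_seq, var_qual = comp1.variable, comp1.variable_qual
        sides = [(var_seq, var_qual, matcher)]

    umi = comp1.umi + (comp2.umi if comp2 is not None else "")

    # 5. quality / N filters
    reason = _quality_filters(var_seq, var_qual, umi, params)
    if reason is not None:
        return reason

    # 6. wild-type matching; sub-checks run in reason order across sides
    matches: list[MatchResult | None] = []
    if any(m is not None for _, _, m in sides):
        for sv, sq, sm in sides:
            res = _match_stage_nearest(sm, sv, params.unit, params.max_mutations)
            if isinstance(res, str):
                return res
            matches.append(res)
        for check, args in (
            (_check_mutation_budget, lambda i: (matches[i], params.unit, params.max_mutations)),
            (_check_mutation_quality, lambda i: (matches[i], sides[i][1], params.min_mutation_quality)),
            (_check_forbidden_codons, lambda i: (matches[i], sides[i][0], params.forbidden_codons)),
        ):
            for i in range(len(sides)):
                reason = check(*args(i))
                if reason is not None:
                    return reason
    else:
        matches = [None for _ in sides]

    # 7. constant-region check (tallies accumulate for both sides)
    ok = True
    const_checked = False
    for comp, refs in (
        (comp1, params.constant_fwd),
        (comp2, params.constant_rev),
    ):
        if comp is None or not comp.constant or not refs:
            continue
        const_checked = True
        passed, match_q, mismatch_q = check_constant(
            comp.constant, comp.constant_qual, refs, params.max_constant_mismatch
        )
        errors.accumulate(match_q, mismatch_q)
        ok = ok and passed
    if const_checked and not ok:
        return F_CONSTANT

    # 8. naming and annotation
    observed = "".join(sv for sv, _, _ in sides) if not merged_mode else var_seq
    if matches[0] is None:
        name = "_".join(sv for sv, _, _ in sides) if len(sides) > 1 else var_seq
        ann = {"sequence": observed}
        return name, umi, observed, ann
    name = "_".join(name_variant(m, params.unit) for m in matches)
    wt_name = "_".join(m.wt_name for m in matches)
    wt_seq = "".join(m.wt_seq for m in matches)
    n_bases = sum(m.n_mut_bases for m in matches)
    n_codons = sum(m.n_mut_codons for m in matches)
    n_aas = None
    types: frozenset[str] = frozenset()
    if all(len(m.wt_seq) % 3 == 0 for m in matches):
        n_aas = 0
        tset: set[str] = set()
        for m, (sv, _, _) in zip(matches, sides):
            prof = classify_mutations(sv, m.wt_seq)
            if prof.n_mut_aas is None:
                n_aas = None
                break
            n_aas += prof.n_mut_aas
            tset |= prof.types
        if n_aas is not None:
            types = frozenset(tset)
    ann = {
        "wildtype": wt_name,
        "sequence": observed,
        "wt_sequence": wt_seq,
        "n_mut_bases": n_bases,
        "n_mut_codons": n_codons,
        "n_mut_aas": n_aas,
        "mutation_types": types,
    }
    return name, umi, observed, ann


def _revcomp_components(comp: ComponentSet) -> None:
    comp.variable = reverse_complement(comp.variable)
    comp.variable_qual = comp.variable_qual[::-1]
    comp.constant = reverse_complement(comp.constant)
    comp.constant_qual = comp.constant_qual[::-1]
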