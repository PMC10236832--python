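"""Joint experiment container and variant annotation.

Per-sample digestion yields one count table per sequencing library.  A MAVE
experiment combines several libraries (input/output, replicates); this
module merges them into one variants × samples count matrix with per-variant
annotation (closest wild-type, number of mutated bases/codons/amino acids,
mutation types) and per-sample metadata plus filtering summaries — the
Python analogue of a SummarizedExperiment-style container, held in pandas
and serialized as a directory of TSV/JSON files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

#: standard genetic code (NCBI translation table 1); '*' = termination
GENETIC_CODE: dict[str, str] = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            GENETIC_CODE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

MUTATION_TYPES = ("silent", "nonsynonymous", "stop")


def translate_dna(seq: str) -> str:
    """Translate an in-frame coding sequence under the standard code.

    Raises ``ValueError`` for a length not divisible by 3 or a codon outside
    the unambiguous DNA alphabet.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    seq = seq.upper()
    try:
        return "".join(GENETIC_CODE[seq[i : i + 3]] for i in range(0, len(seq), 3))
    except KeyError as e:
        raise ValueError(f"untranslatable codon {e.args[0]!r}") from None


class MutationProfile(NamedTuple):
    n_mut_bases: int
    n_mut_codons: int
    n_mut_aas: int | None  # None when the sequences are not in-frame codable
    types: frozenset[str]


def classify_mutations(var_seq: str, wt_seq: str) -> MutationProfile:
    """Count mutated bases/codons/amino acids and label mutation types.

    Codons are read in frame from the first base.  A mutated codon whose
    translation is unchanged contributes ``silent``; one translating to a
    different residue, ``nonsynonymous``; one translating to a termination
    signal, ``stop``.  Amino-acid-level fields are absent (``None`` /
    empty) when the common length is not a multiple of 3.
    """
    if len(var_seq) != len(wt_seq):
        raise ValueError(
            f"sequence lengths differ ({len(var_seq)} vs {len(wt_seq)})"
        )
    var_seq, wt_seq = var_seq.upper(), wt_seq.upper()
    mut_pos = [i for i in range(len(var_seq)) if var_seq[i] != wt_seq[i]]
    codon_idx = sorted({i // 3 for i in mut_pos})
    if len(var_seq) % 3 != 0:
        return MutationProfile(len(mut_pos), len(codon_idx), None, frozenset())
    n_aa = 0
    types: set[str] = set()
    for c in codon_idx:
        vc = var_seq[3 * c : 3 * c + 3]
        wc = wt_seq[3 * c : 3 * c + 3]
        va = GENETIC_CODE.get(vc)
        wa = GENETIC_CODE.get(wc)
        if va is None or wa is None:
            return MutationProfile(len(mut_pos), len(codon_idx), None, frozenset())
        if va == wa:
            types.add("silent")
        elif va == "*":
            types.add("stop")
            n_aa += 1
        else:
            types.add("nonsynonymous")
            n_aa += 1
    return MutationProfile(len(mut_pos), len(codon_idx), n_aa, frozenset(types))


ROW_DATA_COLUMNS = (
    "wildtype",
    "sequence",
    "wtSequence",
    "nMutBases",
    "nMutCodons",
    "nMutAAs",
    "mutationTypes",
)


@dataclass
class Experiment:
    """Variants × samples count container.

    Attributes
    ----------
    counts
        Integer read-count matrix (variants × samples).
    umi_counts
        Matching UMI-count matrix, or ``None`` when the libraries carry no
        UMIs.
    row_data
        Per-variant annotation (closest wild-type, canonical variant and
        wild-type nucleotide sequences, mutation tallies, mutation types as
        a comma-joined string).
    col_data
        Per-sample metadata (replicate, condition, user columns); its index
        order defines the column order of the matrices.
    filter_summaries
        Samples × filter-counter table propagated from digestion.
    param_records
        Per-sample digestion parameter records (JSON-able dicts).
    """

    counts: pd.DataFrame
    umi_counts: pd.DataFrame | None
    row_data: pd.DataFrame
    col_data: pd.DataFrame
    filter_summaries: pd.DataFrame
    param_records: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.row_data.index.equals(self.counts.index):
            raise ValueError("row_data rows must match count-matrix rows")
        if not self.col_data.index.equals(self.counts.columns):
            raise ValueError("col_data rows must match count-matrix columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_variants(self) -> int:
        return self.counts.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def assay(self, which: str = "reads") -> pd.DataFrame:
        if which == "reads":
            return self.counts
        if which == "umis":
            if self.umi_counts is None:
                raise ValueError("experiment has no UMI counts")
            return self.umi_counts
        raise ValueError(f"unknown assay {which!r}")

    # ------------------------------------------------------------------ I/O
    def to_dir(self, path: str | Path) -> None:
        """Serialize as a directory of TSV/JSON files (lossless)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(path / "counts.tsv", sep="\t", index_label="variant")
        if self.umi_counts is not None:
            self.umi_counts.to_csv(
                path / "umi_counts.tsv", sep="\t", index_label="variant"
            )
        self.row_data.to_csv(path / "row_data.tsv", sep="\t", index_label="variant")
        self.col_data.to_csv(path / "col_data.tsv", sep="\t", index_label="sample")
        self.filter_summaries.to_csv(
            path / "filters.tsv", sep="\t", index_label="sample"
        )
        (path / "params.json").write_text(
            json.dumps(self.param_records, indent=2, sort_keys=True)
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "Experiment":
        path = Path(path)
        counts = pd.read_csv(path / "counts.tsv", sep="\t", index_col="variant")
        umi = None
        if (path / "umi_counts.tsv").exists():
            umi = pd.read_csv(path / "umi_counts.tsv", sep="\t", index_col="variant")
        row_data = pd.read_csv(
            path / "row_data.tsv",
            sep="\t",
            index_col="variant",
            dtype={
                "wildtype": "string",
                "sequence": "string",
                "wtSequence": "string",
                "mutationTypes": "string",
            },
        )
        for c in ("nMutBases", "nMutCodons", "nMutAAs"):
            if c in row_data:
                row_data[c] = row_data[c].astype("Int64")
        row_data["mutationTypes"] = row_data["mutationTypes"].fillna("")
        col_data = pd.read_csv(path / "col_data.tsv", sep="\t", index_col="sample")
        filters = pd.read_csv(path / "filters.tsv", sep="\t", index_col="sample")
        params = json.loads((path / "params.json").read_text())
        return cls(counts, umi, row_data, col_data, filters, params)


def merge_samples(
    results: dict[str, "DigestResult"],  # noqa: F821 - duck-typed digest output
    col_data: pd.DataFrame,
) -> Experiment:
    """Merge named per-sample digestion results into one :class:`Experiment`.

    The variant universe is the union over samples; a variant not detected
    in a sample gets a count of 0.  Read counts and, when present in every
    sample, UMI counts are stored as separate matrices.
    """
    names = list(results)
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names")
    if set(names) != set(col_data.index):
        raise ValueError("sample names do not match col_data index")
    col_data = col_data.loc[names]

    variants = sorted({v for r in results.values() for v in r.count_table})
    counts = pd.DataFrame(0, index=pd.Index(variants, name="variant"), columns=names)
    have_umis = all(
        rec.umi_count is not None
        for r in results.values()
        for rec in r.count_table.values()
    ) and any(r.count_table for r in results.values())
    umi = counts.copy() if have_umis else None

    ann: dict[str, dict] = {}
    for s, res in results.items():
        for v, rec in res.count_table.items():
            counts.loc[v, s] = rec.read_count
            if umi is not None:
                umi.loc[v, s] = rec.umi_count
            if v not in ann:
                ann[v] = {
                    "wildtype": rec.wildtype,
                    "sequence": rec.sequence,
                    "wtSequence": rec.wt_sequence,
                    "nMutBases": rec.n_mut_bases,
                    "nMutCodons": rec.n_mut_codons,
                    "nMutAAs": rec.n_mut_aas,
                    "mutationTypes": ",".join(sorted(rec.mutation_types)),
                }
    row_data = pd.DataFrame(
        [ann[v] for v in variants], index=pd.Index(variants, name="variant")
    )
    if not variants:
        row_data = pd.DataFrame(columns=list(ROW_DATA_COLUMNS)).rename_axis("variant")
    for c in ("wildtype", "sequence", "wtSequence", "mutationTypes"):
        row_data[c] = row_data[c].astype("string")
    row_data["mutationTypes"] = row_data["mutationTypes"].fillna("")
    for c in ("nMutBases", "nMutCodons", "nMutAAs"):
        row_data[c] = row_data[c].astype("Int64")
    filters = pd.DataFrame(
        {s: results[s].filter_tally.as_dict() for s in names}
    ).T.rename_axis("sample")
    params = {s: results[s].params_record for s in names}
    return Experiment(counts, umi, row_data[list(ROW_DATA_COLUMNS)], col_data, filters, params)


def _aa_variant_name(wildtype: str | None, wt_aa: str, var_aa: str) -> str:
    diffs = [
        (i + 1, var_aa[i]) for i in range(len(var_aa)) if var_aa[i] != wt_aa[i]
    ]
    base = wildtype if wildtype is not None else wt_aa
    if not diffs:
        return str(base)
    return "_".join(f"{base}.{pos}.{aa}" for pos, aa in diffs)


def collapse_to_aa(exp: Experiment) -> Experiment:
    """Sum counts of variants sharing an identical translated sequence.

    Rows are grouped by (closest wild-type, amino-acid sequence); each group
    becomes one row whose counts are the per-sample sums of its members, so
    every column sum is conserved.  Row annotation is recomputed at the
    amino-acid level.  Untranslatable rows are a hard error.
    """
    bad = []
    groups: dict[tuple, dict] = {}
    for v, row in exp.row_data.iterrows():
        seq = row["sequence"]
        wt_seq = row["wtSequence"]
        try:
            aa = translate_dna(str(seq))
            wt_aa = translate_dna(str(wt_seq)) if pd.notna(wt_seq) else aa
        except (ValueError, TypeError):
            bad.append(v)
            continue
        wt = row["wildtype"] if pd.notna(row["wildtype"]) else None
        key = (wt, aa)
        g = groups.setdefault(key, {"members": [], "wt_aa": wt_aa})
        g["members"].append(v)
    if bad:
        raise ValueError(f"untranslatable variant rows: {bad}")

    rows = []
    names = []
    for (wt, aa), g in groups.items():
        wt_aa = g["wt_aa"]
        diffs = [i for i in range(len(aa)) if aa[i] != wt_aa[i]]
        types = sorted(
            {"stop" if aa[i] == "*" else "nonsynonymous" for i in diffs}
        )
        names.append(_aa_variant_name(wt, wt_aa, aa))
        rows.append(
            {
                "wildtype": wt,
                "sequence": aa,
                "wtSequence": wt_aa,
                "nMutBases": pd.NA,
                "nMutCodons": pd.NA,
                "nMutAAs": len(diffs),
                "mutationTypes": ",".join(types),
                "_members": g["members"],
            }
        )
    order = np.argsort(names, kind="stable")
    names = [names[i] for i in order]
    rows = [rows[i] for i in order]
    if len(set(names)) != len(names):
        raise ValueError("amino-acid variant name collision")

    idx = pd.Index(names, name="variant")
    counts = pd.DataFrame(
        [exp.counts.loc[r["_members"]].sum(axis=0) for r in rows], index=idx
    ).astype(exp.counts.dtypes.iloc[0] if len(exp.counts.columns) else int)
    umi = None
    if exp.umi_counts is not None:
        umi = pd.DataFrame(
            [exp.umi_counts.loc[r["_members"]].sum(axis=0) for r in rows], index=idx
        )
    row_data = pd.DataFrame(
        [{k: v for k, v in r.items() if k != "_members"} for r in rows], index=idx
    )
    for c in ("wildtype", "sequence", "wtSequence", "mutationTypes"):
        row_data[c] = row_data[c].astype("string")
    for c in ("nMutBases", "nMutCodons", "nMutAAs"):
        row_data[c] = row_data[c].astype("Int64")
    return Experiment(
        counts,
        umi,
        row_data[list(ROW_DATA_COLUMNS)],
        exp.col_data,
        exp.filter_summaries,
        exp.param_records,
    )


def sample_correlations(exp: Experiment, assay: str = "reads") -> pd.DataFrame:
    """Pearson correlation of log10(count + 1) between all sample pairs.

    A zero-variance sample yields undefined (NaN) correlations.
    """
    if exp.counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = np.log10(exp.assay(assay).to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    return pd.DataFrame(corr, index=exp.samples, columns=exp.samples)


def filtering_summary(exp: Experiment) -> pd.DataFrame:
    """Long-format table (sample, reason, count, fraction).

    Reasons are the filter counters plus ``retained``; fractions within a
    sample sum to 1 (of its total reads).
    """
    records = []
    for s, row in exp.filter_summaries.iterrows():
        total = row["nTotal"]
        for reason, count in row.items():
            if reason == "nTotal":
                continue
            name = "retained" if reason == "nRetained" else reason
            frac = count / total if total > 0 else np.nan
            records.append(
                {"sample": s, "reason": name, "count": int(count), "fraction": frac}
            )
    return pd.DataFrame.from_records(records)
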