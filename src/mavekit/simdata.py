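"""Deterministic synthetic MAVE data with known ground truth.

Two generators back all end-to-end and statistical testing:

* :func:`simulate_library` writes FASTQ file (pairs) assembled under a read
  layout (skip/UMI/constant/primer/variable segments) from a table of
  variants with known frequencies, optionally injecting per-quality
  sequencing errors and adapter read contamination, and returns the exact
  variant count table expected after error-free digestion.
* :func:`simulate_counts` draws negative-binomial count matrices with
  controlled per-variant group log-fold changes (all-zero = a null design).

Both are fully determined by their seed.  Quality strings are constant per
configured tier (e.g. all Q30) so that error-rate estimates are
analytically checkable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import REMAINDER, ElementSpec

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantSpec:
    """One library member: a wild-type per read side plus codon
    substitutions (1-based codon index, replacement codon)."""

    frequency: float
    wt_fwd: str
    muts_fwd: tuple[tuple[int, str], ...] = ()
    wt_rev: str | None = None
    muts_rev: tuple[tuple[int, str], ...] = ()


@dataclass
class SimConfig:
    """Configuration of a synthetic sequencing library."""

    wildtypes_fwd: dict[str, str]
    layout_fwd: ElementSpec
    variants: list[VariantSpec]
    n_reads: int
    constant_fwd: str = ""
    wildtypes_rev: dict[str, str] | None = None
    layout_rev: ElementSpec | None = None
    constant_rev: str = ""
    umis_per_variant: int = 0  # 0 = a fresh random UMI per read
    qualities: dict[str, int] = field(
        default_factory=lambda: {"variable": 30, "constant": 30, "umi": 30, "skip": 30}
    )
    error_rates: dict[int, float] = field(default_factory=dict)
    adapter_seq: str | None = None
    adapter_rate: float = 0.0
    n_rate: float = 0.0  # per-base probability of an uncalled base (N)
    unit: str = "codon"  # naming convention used in the ground truth
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = [v.frequency for v in self.variants]
        if not freqs or abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("variant frequencies must sum to 1")
        if not 0.0 <= self.adapter_rate <= 1.0:
            raise ValueError("adapter_rate must lie in [0, 1]")
        if not 0.0 <= self.n_rate <= 1.0:
            raise ValueError("n_rate must lie in [0, 1]")
        for q, r in self.error_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"error rate at Q{q} outside [0, 1]")
        if self.adapter_rate > 0 and not self.adapter_seq:
            raise ValueError("adapter_rate > 0 requires adapter_seq")
        if self.unit not in ("base", "codon"):
            raise ValueError("unit must be 'base' or 'codon'")


@dataclass
class SimulatedLibrary:
    fastq_fwd: Path
    fastq_rev: Path | None
    truth: pd.DataFrame  # variant, readCount, umiCount
    n_adapter: int
    config: SimConfig


def _apply_codon_muts(wt: str, muts) -> str:
    seq = list(wt)
    for codon_idx, alt in muts:
        if len(alt) != 3:
            raise ValueError(f"replacement codon {alt!r} must have length 3")
        start = 3 * (codon_idx - 1)
        if start < 0 or start + 3 > len(wt):
            raise ValueError(f"codon index {codon_idx} outside wild-type")
        seq[start : start + 3] = alt
    return "".join(seq)


def _side_name(wt_name: str, wt: str, var: str, unit: str) -> str:
    """Variant identifier as produced by digestion (bare wild-type name for
    an exact match; WT.pos.ALT terms joined by '_')."""
    diffs = [i for i in range(len(wt)) if wt[i] != var[i]]
    if not diffs:
        return wt_name
    if unit == "base":
        return "_".join(f"{wt_name}.{i + 1}.{var[i]}" for i in diffs)
    codons = sorted({i // 3 for i in diffs})
    return "_".join(
        f"{wt_name}.{c + 1}.{var[3 * c : 3 * c + 3]}" for c in codons
    )


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


class _ReadBuilder:
    """Assembles one read side (sequence + quality string) under a layout."""

    def __init__(self, spec: ElementSpec, constant: str, qualities: dict[str, int]):
        self.spec = spec
        self.constant = constant
        self.q = qualities
        c_len = sum(
            l for c, l in zip(spec.codes, spec.lengths) if c == "C" and l != REMAINDER
        )
        if c_len != len(constant):
            raise ValueError(
                f"constant sequence length {len(constant)} does not match the "
                f"layout's constant segments ({c_len})"
            )

    def build(
        self, rng: np.random.Generator, variable: str, umi: str
    ) -> tuple[str, str]:
        seq_parts: list[str] = []
        qual_parts: list[str] = []
        c_used = 0
        u_used = 0
        for code, length in zip(self.spec.codes, self.spec.lengths):
            if code == "V":
                part, tier = variable, "variable"
            elif code == "C":
                if length == REMAINDER:
                    raise ValueError("constant segments must have fixed lengths")
                part, tier = self.constant[c_used : c_used + length], "constant"
                c_used += length
            elif code == "U":
                if length == REMAINDER:
                    raise ValueError("UMI segments must have fixed lengths")
                part, tier = umi[u_used : u_used + length], "umi"
                u_used += length
            elif code == "S":
                n = length if length != REMAINDER else 0
                part, tier = _random_bases(rng, n), "skip"
            elif code == "P":
                part, tier = self.spec.primer_seq or "", "skip"
            seq_parts.append(part)
            qual_parts.append(chr(self.q.get(tier, 30) + 33) * len(part))
        return "".join(seq_parts), "".join(qual_parts)

    def umi_length(self) -> int:
        return sum(
            l for c, l in zip(self.spec.codes, self.spec.lengths) if c == "U"
        )


def _inject_errors(
    rng: np.random.Generator, seq: str, qual: str, error_rates: dict[int, float]
) -> str:
    if not error_rates:
        return seq
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33
    for q, rate in error_rates.items():
        if rate <= 0:
            continue
        at = np.nonzero((quals == q) & (rng.random(len(chars)) < rate))[0]
        for i in at:
            alts = [b for b in b"ACGT" if b != chars[i]]
            chars[i] = alts[rng.integers(0, len(alts))]
    return chars.tobytes().decode("ascii")


def _inject_ns(rng: np.random.Generator, seq: str, n_rate: float) -> str:
    if n_rate <= 0:
        return seq
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    chars[rng.random(len(chars)) < n_rate] = ord("N")
    return chars.tobytes().decode("ascii")


def simulate_library(
    config: SimConfig, out_dir: str | Path, compress: bool = True
) -> SimulatedLibrary:
    """Write a synthetic FASTQ library and its ground-truth count table.

    The truth table holds, per variant name (digestion naming convention),
    the number of reads drawn for it excluding adapter-contaminated reads —
    i.e. the exact count table expected from error-free digestion — and the
    number of distinct UMIs among those reads (when the layout carries
    UMIs).  Deterministic given ``config.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    paired = config.layout_rev is not None

    builder_f = _ReadBuilder(config.layout_fwd, config.constant_fwd, config.qualities)
    builder_r = (
        _ReadBuilder(config.layout_rev, config.constant_rev, config.qualities)
        if paired
        else None
    )
    has_umi = builder_f.umi_length() > 0 or (
        builder_r is not None and builder_r.umi_length() > 0
    )

    # per-variant sequences, names and (optional) UMI pools
    var_seq_f: list[str] = []
    var_seq_r: list[str | None] = []
    names: list[str] = []
    umi_pools: list[list[str]] = []
    total_umi_len = builder_f.umi_length() + (
        builder_r.umi_length() if builder_r else 0
    )
    for v in config.variants:
        wt_f = config.wildtypes_fwd[v.wt_fwd]
        sf = _apply_codon_muts(wt_f, v.muts_fwd)
        name = _side_name(v.wt_fwd, wt_f, sf, config.unit)
        sr = None
        if v.wt_rev is not None:
            if config.wildtypes_rev is None:
                raise ValueError("variant references a reverse wild-type set")
            wt_r = config.wildtypes_rev[v.wt_rev]
            sr = _apply_codon_muts(wt_r, v.muts_rev)
            name = name + "_" + _side_name(v.wt_rev, wt_r, sr, config.unit)
        var_seq_f.append(sf)
        var_seq_r.append(sr)
        names.append(name)
        if config.umis_per_variant > 0 and total_umi_len > 0:
            pool: set[str] = set()
            while len(pool) < config.umis_per_variant:
                pool.add(_random_bases(rng, total_umi_len))
            umi_pools.append(sorted(pool))
        else:
            umi_pools.append([])

    freqs = np.array([v.frequency for v in config.variants])
    choice = rng.choice(len(config.variants), size=config.n_reads, p=freqs)
    adapter_mask = (
        rng.random(config.n_reads) < config.adapter_rate
        if config.adapter_rate > 0
        else np.zeros(config.n_reads, dtype=bool)
    )

    suffix = ".fastq.gz" if compress else ".fastq"
    path_f = out_dir / f"reads_R1{suffix}"
    path_r = out_dir / f"reads_R2{suffix}" if paired else None
    opener = (lambda p: gzip.open(p, "wt")) if compress else (lambda p: open(p, "w"))

    read_counts: dict[str, int] = {}
    umi_sets: dict[str, set] = {}
    n_adapter = 0
    h1 = opener(path_f)
    h2 = opener(path_r) if path_r else None
    try:
        for i in range(config.n_reads):
            k = int(choice[i])
            if umi_pools[k]:
                umi = umi_pools[k][rng.integers(0, len(umi_pools[k]))]
            elif total_umi_len > 0:
                umi = _random_bases(rng, total_umi_len)
            else:
                umi = ""
            umi_f = umi[: builder_f.umi_length()]
            umi_r = umi[builder_f.umi_length() :]
            seq1, qual1 = builder_f.build(rng, var_seq_f[k], umi_f)
            seq1 = _inject_errors(rng, seq1, qual1, config.error_rates)
            seq1 = _inject_ns(rng, seq1, config.n_rate)
            if adapter_mask[i]:
                n_adapter += 1
                assert config.adapter_seq is not None
                seq1 = (config.adapter_seq + seq1)[: len(seq1)]
            else:
                name = names[k]
                read_counts[name] = read_counts.get(name, 0) + 1
                if has_umi:
                    umi_sets.setdefault(name, set()).add(umi)
            h1.write(f"@read{i}\n{seq1}\n+\n{qual1}\n")
            if builder_r is not None:
                seq2, qual2 = builder_r.build(rng, var_seq_r[k] or "", umi_r)
                seq2 = _inject_errors(rng, seq2, qual2, config.error_rates)
                seq2 = _inject_ns(rng, seq2, config.n_rate)
                h2.write(f"@read{i}\n{seq2}\n+\n{qual2}\n")
    finally:
        h1.close()
        if h2 is not None:
            h2.close()

    truth = pd.DataFrame(
        {
            "variant": sorted(read_counts),
            "readCount": [read_counts[v] for v in sorted(read_counts)],
            "umiCount": [
                len(umi_sets[v]) if has_umi else pd.NA for v in sorted(read_counts)
            ],
        }
    )
    truth["umiCount"] = truth["umiCount"].astype("Int64")
    return SimulatedLibrary(path_f, path_r, truth, n_adapter, config)


def simulate_counts(
    n_variants: int,
    group_sizes: tuple[int, ...] | list[int],
    depth: float,
    dispersion: float,
    logfc: np.ndarray | float = 0.0,
    seed: int = 0,
    mean_spread_log2: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Negative-binomial count matrix with per-variant group effects.

    Per-variant baseline means are log-normal around `depth` (log2 sd
    `mean_spread_log2`); samples in the second group have their means
    multiplied by ``2**logfc`` per variant.  ``dispersion = 0`` gives
    Poisson marginals; an all-zero `logfc` is the null design.

    Returns (counts DataFrame, truth dict with the mean matrix ``mu``,
    ``logfc`` and ``groups``).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    group_sizes = tuple(int(g) for g in group_sizes)
    if not group_sizes or any(g < 1 for g in group_sizes):
        raise ValueError("group sizes must be positive")
    lfc = np.broadcast_to(np.asarray(logfc, dtype=float), (n_variants,)).copy()
    if lfc.any() and len(group_sizes) != 2:
        raise ValueError("non-zero log-fold changes need exactly two groups")

    rng = np.random.default_rng(seed)
    base = depth * 2.0 ** rng.normal(0.0, mean_spread_log2, size=n_variants)
    groups: list[str] = []
    labels = "ABCDEFGH"
    for gi, g in enumerate(group_sizes):
        groups += [labels[gi]] * g
    n_samples = sum(group_sizes)
    mu = np.tile(base[:, None], (1, n_samples))
    in_second = np.array([g == labels[1] for g in groups]) if len(group_sizes) > 1 else np.zeros(n_samples, bool)
    mu[:, in_second] *= 2.0 ** lfc[:, None]

    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    idx = pd.Index([f"v{i + 1}" for i in range(n_variants)], name="variant")
    cols = [f"{g}{i + 1}" for i, g in enumerate(groups)]
    df = pd.DataFrame(counts, index=idx, columns=cols)
    return df, {"mu": mu, "logfc": lfc, "groups": groups}
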