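"""Driver/passenger mutation statistics and gene-set enrichment.

SNPs carry a pathogenicity score in [0, 1] (e.g. cancer-weighted FATHMM
output); a score strictly above the classification threshold (default
0.7) marks a driver, anything else a passenger.  A record without a score
stays unclassified, so tables whose overall counts exceed the
driver + passenger sum remain representable.  Summaries report n, mean,
median and sample variance (n-1 denominator) of the scores overall and in
pathway subsets; over-representation of an annotated gene set in the
network's gene sample is tested with the exact upper-tail hypergeometric
probability, accumulated in log space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

DRIVER = "driver"
PASSENGER = "passenger"
UNCLASSIFIED = "unclassified"


@dataclass
class MutationRecord:
    snp_id: str
    gene: str
    score: float | None
    mutation_class: str
    in_metabolic: bool = False


@dataclass
class MutationTable:
    """Classified SNP records plus the threshold they were classified at."""

    records: list
    threshold: float

    def __len__(self):
        return len(self.records)

    def counts(self) -> dict:
        out = {DRIVER: 0, PASSENGER: 0, UNCLASSIFIED: 0}
        for r in self.records:
            out[r.mutation_class] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id,
                    "gene": r.gene,
                    "score": r.score,
                    "class": r.mutation_class,
                    "in_metabolic": r.in_metabolic,
                }
                for r in self.records
            ],
            columns=["snp_id", "gene", "score", "class", "in_metabolic"],
        )


def classify(scores, threshold: float = 0.7) -> MutationTable:
    """Classify ``(snp_id, gene, score)`` triples as driver or passenger.

    Driver iff score > threshold, strictly: a score exactly at the
    threshold is a passenger.  A record with score ``None`` stays
    unclassified.  A score outside [0, 1] is rejected with the record
    index.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    records = []
    for i, (snp, gene, score) in enumerate(scores):
        if score is None or (isinstance(score, float) and math.isnan(score)):
            records.append(MutationRecord(str(snp), str(gene), None,
                                          UNCLASSIFIED))
            continue
        s = float(score)
        if not (0.0 <= s <= 1.0):
            raise ValueError(
                f"record {i}: score {s} outside [0, 1]"
            )
        cls = DRIVER if s > threshold else PASSENGER
        records.append(MutationRecord(str(snp), str(gene), s, cls))
    return MutationTable(records=records, threshold=float(threshold))


def load_mutation_scores(path) -> list:
    """Read a ``snp_id  gene  score`` TSV into classify() input triples."""
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_id", "gene", "score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        (str(s), str(g), None if pd.isna(v) else float(v))
        for s, g, v in df[["snp_id", "gene", "score"]].itertuples(index=False)
    ]


def pathway_flag(table: MutationTable, pathway_genes) -> MutationTable:
    """Flag records whose gene belongs to a pathway gene set."""
    genes = set(pathway_genes)
    records = [
        MutationRecord(r.snp_id, r.gene, r.score, r.mutation_class,
                       in_metabolic=r.gene in genes)
        for r in table.records
    ]
    return MutationTable(records=records, threshold=table.threshold)


def summarize(
    table: MutationTable,
    subset: str = "all",
    pathway_only: bool = False,
    variance_mode: str = "sample",
) -> dict:
    """Score statistics for a class subset, optionally pathway-restricted.

    Returns ``{"n", "mean", "median", "variance"}``; statistics are NaN
    when no scored record is selected, and the variance additionally when
    only one is (sample variance, n-1 denominator; ``variance_mode=
    "population"`` switches to n).
    """
    if subset not in ("all", DRIVER, PASSENGER):
        raise ValueError(f"unknown subset {subset!r}")
    sel = [
        r for r in table.records
        if (subset == "all" or r.mutation_class == subset)
        and (not pathway_only or r.in_metabolic)
    ]
    scores = np.array([r.score for r in sel if r.score is not None])
    n = len(sel)
    if scores.size == 0:
        return {"n": n, "mean": np.nan, "median": np.nan, "variance": np.nan}
    ddof = 1 if variance_mode == "sample" else 0
    var = float(scores.var(ddof=ddof)) if scores.size > ddof else np.nan
    return {
        "n": n,
        "mean": float(scores.mean()),
        "median": float(np.median(scores)),
        "variance": var,
    }


def mutation_summary_table(table: MutationTable, condition: str) -> pd.DataFrame:
    """Per-class summary rows: n_snps, pathway counts, score moments."""
    rows = []
    for subset in ("all", PASSENGER, DRIVER):
        full = summarize(table, subset=subset)
        path = summarize(table, subset=subset, pathway_only=True)
        rows.append({
            "condition": condition,
            "type": subset,
            "n_snps": full["n"],
            "n_snps_pathway": path["n"],
            "mean": full["mean"],
            "median": full["median"],
            "variance": full["variance"],
        })
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    universe_size: int
    annotated_in_universe: int
    sample_size: int
    annotated_in_sample: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "annotated_in_universe": self.annotated_in_universe,
            "sample_size": self.sample_size,
            "annotated_in_sample": self.annotated_in_sample,
            "p_value": self.p_value,
        }


def _log_binom(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    The tail sum is accumulated in log space for numerical stability at
    the extreme p-values gene-set tests produce.
    """
    if N <= 0:
        raise ValueError("empty universe")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    hi = min(n, K)
    if k <= max(0, n + K - N):
        return 1.0
    if k > hi:
        return 0.0
    i = np.arange(k, hi + 1)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(np.exp(logsumexp(log_terms)))


def hypergeometric_enrichment(
    sample_genes, annotated_genes, universe
) -> EnrichmentResult:
    """Over-representation of an annotated gene set in a gene sample.

    Population = the universe, successes = annotated genes in the
    universe, draws = the sample, observed = annotated genes in the
    sample; p = P(X >= observed), upper tail.  Genes outside the universe
    are clipped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sample = set(sample_genes)
    annotated = set(annotated_genes)
    extra = (sample - universe) | (annotated - universe)
    if extra:
        warnings.warn(
            f"{len(extra)} gene(s) outside the universe were clipped",
            stacklevel=2,
        )
        sample &= universe
        annotated &= universe
    N, K, n = len(universe), len(annotated), len(sample)
    k = len(annotated & sample)
    return EnrichmentResult(
        universe_size=N,
        annotated_in_universe=K,
        sample_size=n,
        annotated_in_sample=k,
        p_value=hypergeometric_tail(N, K, n, k),
    )


def load_gene_set(path) -> set:
    """Read a gene-set file: one gene symbol per line, blanks ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
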