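"""Transcript quantification post-processing for cross-species comparison.

Per-sample transcript abundance tables (Salmon ``quant.sf`` layout: Name,
Length, EffectiveLength, TPM, NumReads) are merged, transcript TPMs are
summed into allergen groups via a transcript-to-allergen mapping, and the
allergen x sample matrix is transformed with log2(TPM + 1) for heatmap
display (optionally column-standardized).  Allergen-level TPM differences
between groups are tested with one-way ANOVA plus Tukey's HSD, and p-values
are encoded as significance codes 0-4 (0: p > 0.05 ... 4: p < 0.0001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionTable",
    "HeatmapMatrix",
    "GroupComparison",
    "QUANT_COLUMNS",
    "read_quant",
    "read_mapping",
    "read_samples",
    "aggregate_to_allergen",
    "heatmap_normalize",
    "group_compare",
    "significance_codes",
]

QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


@dataclass
class ExpressionTable:
    """Transcript x sample TPM with allergen and species annotations.

    ``mapping`` has columns transcript_id, allergen, species; ``samples`` has
    columns sample_id, species, tissue (index on sample_id is set lazily).
    """

    tpm: pd.DataFrame  # transcripts (index) x samples (columns)
    mapping: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        for req, df, name in (
            ({"transcript_id", "allergen", "species"}, self.mapping, "mapping"),
            ({"sample_id", "species", "tissue"}, self.samples, "samples"),
        ):
            missing = req - set(df.columns)
            if missing:
                raise ValueError(f"{name} table missing columns {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        unknown = set(self.tpm.columns) - set(self.samples["sample_id"])
        if unknown:
            raise ValueError(f"samples sheet missing entries for {sorted(unknown)}")

    @property
    def allergens(self) -> list[str]:
        return sorted(self.mapping["allergen"].unique())

    def sample_species(self, sample_id: str) -> str:
        row = self.samples[self.samples["sample_id"] == sample_id]
        return str(row["species"].iloc[0])

    def muscle_samples(self) -> list[str]:
        """Samples not flagged as mixed tissue (kept for cross-species tests)."""
        keep = self.samples[self.samples["tissue"] != "mixed"]["sample_id"]
        return [s for s in self.tpm.columns if s in set(keep)]


def read_quant(
    paths: Mapping[str, str | Path],
    mapping: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
) -> ExpressionTable | pd.DataFrame:
    """Merge per-sample ``quant.sf`` files keyed by transcript Name.

    ``paths`` maps sample_id -> quant.sf path.  Transcripts missing from a
    sample get TPM 0 (with a warning).  When ``mapping`` and ``samples`` are
    given an :class:`ExpressionTable` is returned, otherwise the raw merged
    transcript x sample TPM frame.
    """
    columns = {}
    for sample_id, path in paths.items():
        df = pd.read_csv(path, sep="\t")
        if list(df.columns) != QUANT_COLUMNS:
            raise ValueError(
                f"{path}: malformed quant header {list(df.columns)}; "
                f"expected {QUANT_COLUMNS}"
            )
        columns[sample_id] = df.set_index("Name")["TPM"].astype(float)
    merged = pd.DataFrame(columns)
    if merged.isna().any().any():
        for sample_id in merged.columns:
            n_missing = int(merged[sample_id].isna().sum())
            if n_missing:
                warnings.warn(
                    f"sample {sample_id!r}: {n_missing} transcript(s) absent "
                    "from quant file; imputing TPM 0",
                    stacklevel=2,
                )
        merged = merged.fillna(0.0)
    if mapping is None or samples is None:
        return merged
    return ExpressionTable(merged, mapping, samples)


def read_mapping(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def read_samples(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def aggregate_to_allergen(t: ExpressionTable) -> pd.DataFrame:
    """Allergen x sample TPM, summing member transcripts per sample.

    The mapping is species-aware: an allergen with no mapped transcript for a
    sample's species is reported as missing (NaN), not zero.  Unmapped
    transcripts are excluded.
    """
    mapping = t.mapping.set_index("transcript_id")
    mapped = [tx for tx in t.tpm.index if tx in mapping.index]
    allergen_of = mapping.loc[mapped, "allergen"]
    sums = t.tpm.loc[mapped].groupby(allergen_of).sum()
    sums = sums.reindex(index=t.allergens)

    covered = mapping.groupby("species")["allergen"].agg(set)
    for sample_id in sums.columns:
        species = t.sample_species(sample_id)
        present = covered.get(species, set())
        absent = [a for a in sums.index if a not in present]
        sums.loc[absent, sample_id] = np.nan
    return sums


@dataclass
class HeatmapMatrix:
    values: pd.DataFrame  # allergen x sample
    normalization: str

    def __post_init__(self) -> None:
        finite = np.isfinite(self.values.to_numpy())
        missing = self.values.isna().to_numpy()
        if not (finite | missing).all():
            raise ValueError("heatmap values must be finite (NaN allowed for missing)")


def heatmap_normalize(
    m: pd.DataFrame, scale_columns: bool = False, pseudocount: float = 1.0
) -> HeatmapMatrix:
    """log2(TPM + pseudocount), optionally z-scoring each sample column.

    With the default pseudocount 1 a TPM of 0 maps to 0 and a sample fully
    dominated by one transcript tops out near log2(1e6) ~ 20, matching the
    usual 0-20 display range for TPM heatmaps.
    """
    if (m.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = np.log2(m + pseudocount)
    desc = f"log2(TPM+{pseudocount:g})"
    if scale_columns:
        centered = values - values.mean(axis=0)
        sd = values.std(axis=0, ddof=1).replace(0.0, 1.0)
        values = centered / sd
        desc += ", column-standardized"
    return HeatmapMatrix(values, desc)


@dataclass
class GroupComparison:
    f_statistic: float
    anova_p: float
    pairwise_p: pd.DataFrame  # symmetric group x group matrix of Tukey HSD p-values


def group_compare(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA across groups followed by Tukey HSD pairwise p-values."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for name in names:
        arr = np.asarray(list(groups[name]), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than two observations")
        arrays.append(arr)
    with warnings.catch_warnings():
        # constant inputs give 0/0 F statistics; treated as no separation below
        warnings.simplefilter("ignore", RuntimeWarning)
        f_stat, p = stats.f_oneway(*arrays)
        tukey = stats.tukey_hsd(*arrays)
    if np.isnan(f_stat):  # all values identical within and across groups
        f_stat, p = 0.0, 1.0
    pairwise = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i in range(len(names)):
        for j in range(len(names)):
            if i != j:
                pv = float(tukey.pvalue[i, j])
                pairwise.iloc[i, j] = 1.0 if np.isnan(pv) else pv
    return GroupComparison(float(f_stat), float(p), pairwise)


_CODE_BOUNDS = (0.05, 0.01, 0.001, 0.0001)


def significance_codes(p_values):
    """Map p-values to codes 0-4 (0: p > 0.05 ... 4: p < 0.0001).

    The code is the largest k whose strict inequality p < bound_k holds, so a
    p exactly at a boundary takes the weaker code (p = 0.05 -> 0).  Accepts a
    scalar, a sequence, or a DataFrame (NaN passes through as NaN).
    """
    if isinstance(p_values, pd.DataFrame):
        return p_values.map(significance_codes)
    if np.ndim(p_values) > 0:
        return np.array([significance_codes(p) for p in np.asarray(p_values).ravel()]).reshape(
            np.shape(p_values)
        )
    p = float(p_values)
    if np.isnan(p):
        return np.nan
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    code = 0
    for k, bound in enumerate(_CODE_BOUNDS, start=1):
        if p < bound:
            code = k
    return code
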