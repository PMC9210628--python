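"""Pathway-level tumor mutation burden (TMB).

TMB for a pathway is the number of qualifying somatic mutations in the
pathway's genes per megabase of coding sequence in those genes.  It is
carried in three forms: a raw count, the per-Mb rate, and a binary
any-mutation flag; for use as a continuous exposure the per-Mb rate is
log2-transformed with a pseudocount of half the minimal observable burden
(the rate of a single mutation in the pathway, divided by two), which keeps
zero-burden samples finite while preserving the per-doubling reading of a
log2-scale coefficient.

A gene shared by k pathways contributes its mutations to each of the k
pathway burdens; use :meth:`PathwayCollection.drop_shared_genes` for the
exclusive-gene sensitivity analysis.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import PathwayCollection

#: Nonsynonymous coding variant classes counted by default (MAF vocabulary).
DEFAULT_INCLUDED_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

MAF_COLUMNS = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a MAF-dialect TSV (comment lines start with '#').

    Only the sample barcode, gene symbol and variant classification columns
    are required; anything else is passed through untouched.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF {Path(path).name} lacks column(s): {', '.join(missing)}")
    return df


def write_maf(mutations: pd.DataFrame, path: str | Path) -> None:
    mutations.to_csv(path, sep="\t", index=False)


def default_pseudocount(total_coding_length_bp: int) -> float:
    """Half the per-Mb rate of a single mutation in the pathway."""
    return 0.5 / (total_coding_length_bp / 1e6)


def compute_tmb(
    mutations: pd.DataFrame,
    coll: PathwayCollection,
    samples: Sequence[str],
    included_classes: Iterable[str] = DEFAULT_INCLUDED_CLASSES,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-sample, per-pathway mutation burden.

    Parameters
    ----------
    mutations
        MAF-like frame with ``Tumor_Sample_Barcode``, ``Hugo_Symbol``,
        ``Variant_Classification`` columns.
    samples
        Every id listed here appears in the output, including zero-mutation
        samples.  Mutation records for samples *not* in this list trigger a
        warning and are excluded.
    included_classes
        Variant classes that qualify; everything else is filtered first.
    pseudocount
        Added to ``tmb_per_mb`` inside the log2; per-pathway default is half
        the minimal observable burden.

    Returns
    -------
    Long-format frame: sample_id, pathway, n_mutations, tmb_per_mb,
    any_mutation, log2_tmb.
    """
    samples = list(samples)
    sample_set = set(samples)
    if len(sample_set) != len(samples):
        raise ValueError("duplicate sample ids in samples list")

    included = set(included_classes)
    df = mutations[MAF_COLUMNS].copy()
    df = df[df["Variant_Classification"].isin(included)]

    stray = sorted(set(df["Tumor_Sample_Barcode"]) - sample_set)
    if stray:
        warnings.warn(
            f"{len(stray)} sample(s) present in mutations but not in the "
            f"sample list were excluded: {', '.join(stray[:5])}"
            + ("..." if len(stray) > 5 else ""),
            stacklevel=2,
        )
        df = df[df["Tumor_Sample_Barcode"].isin(sample_set)]

    rows = []
    for p in coll:
        sub = df[df["Hugo_Symbol"].isin(p.genes)]
        counts = sub.groupby("Tumor_Sample_Barcode").size()
        n = counts.reindex(samples, fill_value=0).to_numpy()
        length_mb = p.total_coding_length_mb
        tmb = n / length_mb
        pc = pseudocount if pseudocount is not None else default_pseudocount(
            p.total_coding_length_bp
        )
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "pathway": p.name,
                    "n_mutations": n,
                    "tmb_per_mb": tmb,
                    "any_mutation": n > 0,
                    "log2_tmb": np.log2(tmb + pc),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def tmb_wide(tmb_table: pd.DataFrame, value: str = "any_mutation") -> pd.DataFrame:
    """Pivot the long TMB table to samples x pathways for one burden form."""
    wide = tmb_table.pivot(index="sample_id", columns="pathway", values=value)
    if value == "any_mutation":
        wide = wide.astype(float)
    return wide
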