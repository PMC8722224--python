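"""End-to-end convenience: counts -> per-GATC stats -> peaks -> gene calls."""

from __future__ import annotations

import pandas as pd

from .differential import differential_gatc
from .genome import GatcMap, GeneSet
from .peaks import call_peaks


def run_pipeline(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    gatc: GatcMap,
    genes: GeneSet,
    treatment: str,
    reference: str = "Dam",
    p_site: float = 1e-5,
    fdr_threshold: float = 0.01,
    tolerance: int | None = None,
    pseudocount: float = 1.0,
):
    """Run the full differential-occupancy pipeline for one contrast.

    ``samples`` maps each count column to a condition; the contrast is
    treatment vs. reference (Dam-only).  Returns (stats, peaks, assignments):
    the per-fragment statistic table, the scored peaks, and the per-gene
    minimum-FDR assignment table with the significance call at
    ``fdr_threshold``.
    """
    fusion = samples.loc[samples["condition"] == treatment, "sample"].tolist()
    dam = samples.loc[samples["condition"] == reference, "sample"].tolist()
    if not fusion or not dam:
        raise ValueError(f"no samples for contrast {treatment} vs {reference}")
    stats = differential_gatc(counts, fusion, dam, pseudocount=pseudocount, p_threshold=p_site)
    peaks, assignments = call_peaks(
        stats, gatc, genes, tolerance=tolerance, p_site=p_site, fdr_threshold=fdr_threshold
    )
    return stats, peaks, assignments
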