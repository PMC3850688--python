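"""End-to-end convenience drivers over the library modules.

These wire the simulator, mapper, caller and summarizers together for the
common simulate -> align -> call -> summarize workflow, and provide the
truth-comparison metrics used to validate parameter recovery.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import bsalign, bscall, refmodel, simulate
from .simulate import MethylomeTruth, SimConfig

__all__ = ["run_bs_pipeline", "evaluate_against_truth"]


def run_bs_pipeline(
    config: SimConfig,
    chh_filter: bool = False,
    params: Optional[bscall.CallModelParams] = None,
) -> dict:
    """Simulate a study and run it through mapping, pileup and calling.

    Returns a dict with the genome, gene models, region index, planted
    truth, alignments, pileup and the per-cytosine call table.
    """
    genome, genes = simulate.simulate_genome(config)
    index = refmodel.build_region_index(
        genes, genome, flank=config.flank, splice_site=config.splice_site
    )
    truth = simulate.plant_methylome(genome, genes, config, index)
    reads = simulate.simulate_bs_reads(genome, truth, config)
    alignments = bsalign.map_bs_reads(genome, reads)
    pileup = bscall.build_pileup(alignments, genome, chh_filter=chh_filter)
    if params is None:
        params = bscall.CallModelParams(conv_fail=config.conv_fail)
    calls = bscall.call_all(pileup, genome, params)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "index": index,
        "truth": truth,
        "reads": reads,
        "alignments": alignments,
        "pileup": pileup,
        "calls": calls,
    }


def evaluate_against_truth(
    calls: pd.DataFrame, truth: MethylomeTruth, min_depth: int = 10
) -> dict:
    """Per-site level accuracy and false-modification rate versus the truth.

    accuracy: fraction of called sites with depth >= min_depth whose level
    equals the planted level.  false_modification_rate: fraction of those
    sites planted unmodified that were called modified.
    """
    sub = calls[calls["depth"] >= min_depth]
    if len(sub) == 0:
        return {"accuracy": float("nan"), "false_modification_rate": float("nan"), "n": 0}
    planted = np.empty(len(sub))
    pos = sub["pos"].to_numpy()
    chroms = sub["chrom"].to_numpy()
    strands = sub["strand"].to_numpy()
    for chrom in np.unique(chroms):
        for strand in "+-":
            m = (chroms == chrom) & (strands == strand)
            if m.any():
                planted[m] = truth.level_array(chrom, strand)[pos[m]]
    called = sub["level"].to_numpy()
    accuracy = float(np.mean(called == planted))
    planted_zero = planted == 0
    fmr = (
        float(np.mean(called[planted_zero] > 0)) if planted_zero.any() else float("nan")
    )
    return {
        "accuracy": accuracy,
        "false_modification_rate": fmr,
        "n": int(len(sub)),
        "n_planted_zero": int(planted_zero.sum()),
    }
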