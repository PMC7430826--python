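"""End-to-end study recipes, fully synthetic.

These functions wire the generator, database, and detector into the two
identification experiments the package is built around, at desk scale:

* take-one-out: three conspecific plastome accessions (pairwise divergence
  <= 0.1%) among diverged relatives; three k=31 databases each omitting one
  accession; the omitted accession's reads must rank the true taxon first.
* spike-in dilution: a 220,000-read background mixture (three plant pools
  at 30% each, three bacterial pools at 3.3% each) spiked with target
  plastome reads over a 5% -> 0.01% dilution series, three replicates; the
  limit of detection is the smallest fraction supported in all replicates.

Everything is deterministic in ``seed``.  Derived seeds are kept distinct
per purpose (genomes / reads / mixtures) by fixed offsets.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .detection import detect, dilution_series, limit_of_detection, take_one_out_accuracy
from .refdb import build_database, take_one_out
from .synthetic import (
    DILUTION_FRACTIONS,
    PAPER_BACKGROUND,
    MixtureComponent,
    normalize_proportions,
    simulate_genome,
    simulate_panel,
    simulate_reads,
)

__all__ = ["run_take_one_out_study", "run_dilution_study", "build_phylogeny_panel_db"]

GENOME_LEN = 158_900  # plastome-scale circular genome
READ_LEN = 125
ERROR_RATE = 0.002
K_ID = 31


def build_phylogeny_panel_db(seed: int, k: int = K_ID):
    """Simulate the reference panel and build the full k=31 database."""
    panel = simulate_panel(seed)
    triples = panel["target"] + panel["relatives"] + panel["outgroup"]
    db = build_database(triples, k=k, canonical=True, circular=True)
    return panel, db


def run_take_one_out_study(
    seed: int = 0,
    reads_per_trial: int = 10_000,
    n_relatives_check: int = 5,
    **detect_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Take-one-out identification over three conspecific accessions.

    Returns ``(accuracy_percent, per_trial_table)``.  Accuracy is the
    percent of trials in which the held-out accession's reads rank the
    "target" taxon first among detected taxa.
    """
    panel, db = build_phylogeny_panel_db(seed)
    assert len(panel["relatives"]) >= n_relatives_check
    accession_ids = [gid for _, gid, _ in panel["target"]]
    genome_of = {gid: rec for _, gid, rec in panel["target"]}

    dbs = [take_one_out(db, gid) for gid in accession_ids]
    read_sets = [
        simulate_reads(
            genome_of[gid], reads_per_trial, read_len=READ_LEN,
            error_rate=ERROR_RATE, seed=seed + 1000 + i,
        )
        for i, gid in enumerate(accession_ids)
    ]
    accuracy, reports = take_one_out_accuracy(dbs, read_sets, "target", **detect_kwargs)
    rows = []
    for gid, rep in zip(accession_ids, reports):
        res = rep.per_taxon.get("target")
        rows.append(
            {
                "held_out": gid,
                "top_taxon": rep.top_taxon(),
                "correct": rep.top_taxon() == "target",
                "target_assigned_reads": res.assigned_reads if res else 0,
                "target_unique_kmers": res.unique_matched_kmers if res else 0,
                "target_support_p": res.support_p if res else 1.0,
            }
        )
    return accuracy, pd.DataFrame(rows)


def _background_pools(seed: int, total_reads: int, design=None) -> list[MixtureComponent]:
    """Simulate background genomes and read pools sized for the mixture.

    Plant components get plastome-scale genomes; bacterial components get
    larger (4 Mb-scale) genomes, as in a genomic "contaminant".  Pool
    sizes carry ~2% headroom over the largest background share.
    """
    design = normalize_proportions(design or PAPER_BACKGROUND)
    comps = []
    for i, (label, prop) in enumerate(design):
        g_len = GENOME_LEN if label.startswith("plant") else 1_000_000
        genome = simulate_genome(g_len, seed=seed + 10 + i, id=label)
        n_pool = int(np.ceil(total_reads * prop / 100.0 * 1.02)) + 10
        reads = simulate_reads(
            genome, n_pool, read_len=READ_LEN, error_rate=ERROR_RATE, seed=seed + 100 + i
        )
        comps.append(MixtureComponent(label, reads, prop))
    return comps


def run_dilution_study(
    seed: int = 0,
    total_reads: int = 220_000,
    replicates: int = 3,
    fractions=None,
    config: Optional[dict] = None,
    **detect_kwargs,
) -> tuple[pd.DataFrame, Optional[float]]:
    """Spike-in dilution series against a take-one-out database.

    The spiked reads come from one conspecific accession; the database
    omits that accession (so detection relies on the other accessions of
    the taxon plus the relatives), mirroring the take-one-out design.
    Returns the tidy dilution table and the limit of detection (smallest
    fraction supported in all replicates, or None).
    """
    fractions = list(fractions if fractions is not None else DILUTION_FRACTIONS)
    cfg = config or {}
    panel, db = build_phylogeny_panel_db(seed)
    spike_accession = panel["target"][0]
    db_loo = take_one_out(db, spike_accession[1])

    max_frac = max(fractions)
    n_target_pool = int(np.ceil(total_reads * max_frac / 100.0)) + 10
    target_reads = simulate_reads(
        spike_accession[2], n_target_pool, read_len=READ_LEN,
        error_rate=ERROR_RATE, seed=seed + 500,
    )
    background = _background_pools(
        seed, total_reads,
        design=[(c["label"], c["proportion"]) for c in cfg["background"]] if cfg.get("background") else None,
    )
    table = dilution_series(
        db_loo,
        background,
        target_reads,
        "target",
        fractions,
        total_reads=total_reads,
        seed=seed,
        replicates=replicates,
        **detect_kwargs,
    )
    return table, limit_of_detection(table)
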