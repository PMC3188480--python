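#!/usr/bin/env python
"""Subgroup analyses on real structures: amino acids and nucleotides.

Joins the fixture-structure descriptors (02_fixture_descriptors.py) with
concentrations drawn from the study-condition linear model, then asks two
sharper questions: how strongly does NPSA alone explain amino-acid
concentrations, and how much does each additional phosphate group raise
nucleotide concentrations?
"""

import json
import math
from pathlib import Path

import numpy as np

from metaconc import GeneratorConfig
from metaconc.groups import AMINO_ACIDS, PHOSPHATE_COUNTS
from metaconc.io import read_descriptor_table
from metaconc.stats import ConcentrationDataset, filter_small, per_phosphate_fold, subgroup_correlations

ROOT = Path(__file__).resolve().parent.parent / "results"
N_REPLICATES = 21


def main():
    descriptors = read_descriptor_table(ROOT / "descriptors_fixtures.tsv")
    cfg = GeneratorConfig()
    rng = np.random.default_rng(1)
    mean_log10 = (
        cfg.intercept
        + cfg.beta_npsa * descriptors["NPSA"].to_numpy()
        + cfg.beta_nca * descriptors["NCA"].to_numpy()
    )

    aa_r2, folds = [], []
    for _ in range(N_REPLICATES):
        y = mean_log10 + rng.normal(0.0, cfg.sigma, len(descriptors))
        ds = ConcentrationDataset("fixtures", "c", dict(zip(descriptors.index, 10.0**y)))
        small, _ = filter_small(ds, descriptors)
        aa_r2.append(subgroup_correlations(small, AMINO_ACIDS, "NPSA").r2)
        full, _ = filter_small(ds, descriptors, mw_max=1e9)
        folds.append(math.log10(per_phosphate_fold(full, PHOSPHATE_COUNTS)))

    out = {
        "n_replicate_conditions": N_REPLICATES,
        "amino_acid_npsa_r2_mean": float(np.mean(aa_r2)),
        "amino_acid_npsa_r2_min": float(np.min(aa_r2)),
        "fold_per_phosphate_geomean": float(10.0 ** np.mean(folds)),
    }
    (ROOT / "subgroups.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote subgroup summary -> {ROOT/'subgroups.json'}")
    print(
        f"amino-acid NPSA R^2: mean {out['amino_acid_npsa_r2_mean']:.2f} over "
        f"{N_REPLICATES} replicate conditions (n = 20 amino acids each)"
    )
    print(
        f"each additional phosphate group changes concentration "
        f"{out['fold_per_phosphate_geomean']:.1f}-fold (AMP/ADP/ATP series; the "
        "charge gain and the shrinking non-polar surface both push upward)"
    )


if __name__ == "__main__":
    main()
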