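#!/usr/bin/env python
"""Draw the synthetic multi-condition compendium and write it to disk.

Emulates a metabolomics compendium of 21 independently measured conditions
over 93 metabolites, with log10 concentrations generated from the linear
NPSA+NCA model plus log-scale noise (sigma = 0.75).
"""

from pathlib import Path

from metaconc import GeneratorConfig, generate_table
from metaconc.io import write_concentration_table, write_descriptor_table

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main():
    cfg = GeneratorConfig(seed=SEED)
    descriptors, datasets, truth = generate_table(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_descriptor_table(descriptors, OUT / "descriptors.tsv")
    write_concentration_table(datasets, OUT / "concentrations.tsv")
    print(
        f"wrote {len(descriptors)} metabolites x {len(datasets)} conditions to {OUT}\n"
        f"generating model: log10 c = {truth['intercept']} "
        f"+ ({truth['beta_npsa']})*NPSA + ({truth['beta_nca']})*NCA "
        f"+ N(0, {truth['sigma']})"
    )


if __name__ == "__main__":
    main()
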