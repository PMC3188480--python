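"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a multi-condition metabolomics compendium: a
descriptor table with realistic ranges and log10 concentrations drawn from
a linear model in NPSA and NCA plus Gaussian (log-scale) noise,

    log10 c = intercept + beta_npsa * NPSA + beta_nca * NCA + N(0, sigma),

independently re-drawn for every condition.  Defaults place the cohort in
the empirically observed regime: a Bennett-sized condition (93 metabolites),
21 conditions, a ~100-fold concentration span across the NPSA range and
roughly half the log-concentration variance explained by NPSA and NCA.

The module also packages ~35 real small-metabolite structures (amino acids,
central-carbon acids, adenine nucleotides) as SMILES for integration tests
of the descriptor machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem.molecule import MoleculeRecord
from .stats import ConcentrationDataset


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Units: betas are log10-concentration per Å² (NPSA) and per charged atom
    (NCA); the intercept and sigma are in log10 mol/L.
    """

    n_metabolites: int = 93
    beta_npsa: float = -0.01
    beta_nca: float = 0.25
    intercept: float = -3.5
    sigma: float = 0.75
    npsa_range: tuple[float, float] = (20.0, 220.0)
    nca_dist: tuple[float, ...] = (0.30, 0.30, 0.20, 0.12, 0.08)  # weights for NCA 0..4
    mw_range: tuple[float, float] = (50.0, 300.0)
    n_conditions: int = 21
    seed: int = 1

    def __post_init__(self):
        if self.n_metabolites < 1 or self.n_conditions < 1:
            raise ValueError("n_metabolites and n_conditions must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not (self.npsa_range[0] < self.npsa_range[1]) or not (
            self.mw_range[0] < self.mw_range[1]
        ):
            raise ValueError("ranges must be ordered (min < max)")
        if abs(sum(self.nca_dist) - 1.0) > 1e-9 or any(w < 0 for w in self.nca_dist):
            raise ValueError("nca_dist weights must be non-negative and sum to 1")


def generate_table(
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[pd.DataFrame, list[ConcentrationDataset], dict]:
    """Draw one synthetic cohort.

    Returns the descriptor table (indexed by id), one
    :class:`ConcentrationDataset` per condition, and the generating
    parameters for recovery tests.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_metabolites
    ids = [f"synth-{i:03d}" for i in range(1, n + 1)]

    npsa = rng.uniform(*cfg.npsa_range, size=n)
    nca = rng.choice(len(cfg.nca_dist), size=n, p=np.asarray(cfg.nca_dist))
    mw = rng.uniform(*cfg.mw_range, size=n)

    # companion descriptors: plausible, correlated, not chemically realizable
    psa = np.clip(15.0 + 18.0 * nca + rng.normal(0.0, 12.0, n), 0.0, None)
    hbd = np.clip(np.round(psa / 25.0 + rng.normal(0, 0.5, n)), 0, None).astype(int)
    hba = np.clip(np.round(psa / 15.0 + rng.normal(0, 0.5, n)), 0, None).astype(int)
    nrb = np.clip(np.round(mw / 60.0 + rng.normal(0, 1.0, n)), 0, None).astype(int)
    logp = -2.0 + 0.015 * npsa - 0.8 * nca + rng.normal(0.0, 0.5, n)
    logs = 0.5 - 0.01 * npsa + 0.5 * nca + rng.normal(0.0, 0.5, n)

    descriptors = pd.DataFrame(
        {
            "name": ids,
            "MW": mw,
            "PSA": psa,
            "NPSA": npsa,
            "NCA": nca,
            "HBD": hbd,
            "HBA": hba,
            "HBI": hbd + hba,
            "NRB": nrb,
            "LogP": logp,
            "LogS": logs,
        },
        index=pd.Index(ids, name="id"),
    )

    mean_log10 = cfg.intercept + cfg.beta_npsa * npsa + cfg.beta_nca * nca
    datasets = []
    for c in range(1, cfg.n_conditions + 1):
        log10c = mean_log10 + rng.normal(0.0, cfg.sigma, size=n)
        datasets.append(
            ConcentrationDataset(
                source="synthetic",
                condition=f"cond-{c:02d}",
                entries=dict(zip(ids, 10.0**log10c)),
                metadata={"organism": "synthetic", "platform": "generator"},
            )
        )

    truth = {
        "beta_npsa": cfg.beta_npsa,
        "beta_nca": cfg.beta_nca,
        "intercept": cfg.intercept,
        "sigma": cfg.sigma,
        "mean_log10": mean_log10,
    }
    return descriptors, datasets, truth


# ------------------------------------------------------------------ fixtures
# (id, name, neutral-form SMILES); protonation to pH 7 happens downstream
_FIXTURE_SMILES: tuple[tuple[str, str, str], ...] = (
    ("glycine", "Glycine", "NCC(=O)O"),
    ("alanine", "L-Alanine", "CC(N)C(=O)O"),
    ("valine", "L-Valine", "CC(C)C(N)C(=O)O"),
    ("leucine", "L-Leucine", "CC(C)CC(N)C(=O)O"),
    ("isoleucine", "L-Isoleucine", "CCC(C)C(N)C(=O)O"),
    ("proline", "L-Proline", "OC(=O)C1CCCN1"),
    ("phenylalanine", "L-Phenylalanine", "NC(Cc1ccccc1)C(=O)O"),
    ("tryptophan", "L-Tryptophan", "NC(Cc1c[nH]c2ccccc12)C(=O)O"),
    ("methionine", "L-Methionine", "CSCCC(N)C(=O)O"),
    ("serine", "L-Serine", "NC(CO)C(=O)O"),
    ("threonine", "L-Threonine", "CC(O)C(N)C(=O)O"),
    ("cysteine", "L-Cysteine", "NC(CS)C(=O)O"),
    ("tyrosine", "L-Tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O"),
    ("asparagine", "L-Asparagine", "NC(=O)CC(N)C(=O)O"),
    ("glutamine", "L-Glutamine", "NC(=O)CCC(N)C(=O)O"),
    ("aspartate", "L-Aspartate", "NC(CC(=O)O)C(=O)O"),
    ("glutamate", "L-Glutamate", "NC(CCC(=O)O)C(=O)O"),
    ("lysine", "L-Lysine", "NCCCCC(N)C(=O)O"),
    ("arginine", "L-Arginine", "NC(CCCNC(=N)N)C(=O)O"),
    ("histidine", "L-Histidine", "NC(Cc1c[nH]cn1)C(=O)O"),
    ("pyruvate", "Pyruvate", "CC(=O)C(=O)O"),
    ("lactate", "L-Lactate", "CC(O)C(=O)O"),
    ("acetate", "Acetate", "CC(=O)O"),
    ("succinate", "Succinate", "OC(=O)CCC(=O)O"),
    ("fumarate", "Fumarate", "OC(=O)/C=C/C(=O)O"),
    ("malate", "L-Malate", "OC(CC(=O)O)C(=O)O"),
    ("citrate", "Citrate", "OC(=O)CC(O)(CC(=O)O)C(=O)O"),
    ("2-ketoglutarate", "2-Ketoglutarate", "OC(=O)CCC(=O)C(=O)O"),
    ("oxaloacetate", "Oxaloacetate", "OC(=O)CC(=O)C(=O)O"),
    ("glucose", "D-Glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("glucose-6-phosphate", "D-Glucose 6-phosphate", "OC1OC(COP(=O)(O)O)C(O)C(O)C1O"),
    ("pep", "Phosphoenolpyruvate", "C(=C)(OP(=O)(O)O)C(=O)O"),
    ("3pg", "3-Phosphoglycerate", "OC(=O)C(O)COP(=O)(O)O"),
    ("amp", "AMP", "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)O)C(O)C1O"),
    ("adp", "ADP", "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)O)C(O)C1O"),
    ("atp", "ATP", "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O"),
)


def fixture_molecules() -> list[MoleculeRecord]:
    """Packaged common-metabolite structures for descriptor integration tests."""
    return [
        MoleculeRecord.from_smiles(smiles, id=mol_id, name=name)
        for mol_id, name, smiles in _FIXTURE_SMILES
    ]
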