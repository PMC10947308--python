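#!/usr/bin/env python
"""Morphology analyses on simulated field data.

Trains the discriminant morphology index on two-species character tables,
summarizes PCA structure, estimates index heritability from maternal
families, and regresses population admixture and morphological intermediacy
on distance to the nearest heterospecific population.
"""
import sys
from pathlib import Path

import numpy as np

from snapmap import morpho, simcross
from snapmap.core_io import AnalysisConfig, write_results

RUN = Path(__file__).resolve().parents[1] / "results" / "run"
SEED = 1

CHARACTERS = ["PlHt", "IntL", "BrIn", "LfLW", "LfA",
              "NFl", "FlL", "SepL", "PetAn", "PetL"]


def main() -> int:
    rng = np.random.default_rng(SEED)
    RUN.mkdir(parents=True, exist_ok=True)

    # discriminant index on simulated least-admixed plants of each species
    z, labels = simcross.simulate_species_characters(
        (60, 60), CHARACTERS, separation=2.0, rng=rng, correlated=True)
    weights = morpho.train_discriminant(z, labels)
    index = morpho.morphology_index(z, weights)
    loadings, varfrac = morpho.pca_characters(z)

    # heritability of the index from maternal families
    fams = simcross.simulate_maternal_families(0.6, 30, 8, rng)
    h2 = morpho.heritability_by_mother(fams["value"].to_numpy(),
                                       fams["family"].to_numpy())

    # landscape: admixture and morphological intermediacy vs distance
    site = simcross.simulate_landscape(rng=rng)
    regressions = morpho.distance_regressions(site)

    payload = {
        "index_weights": dict(zip(weights.characters,
                                  np.round(weights.weights, 4))),
        "index_class_means": {
            c: float(index[labels.to_numpy() == c].mean())
            for c in sorted(labels.unique())},
        "pc1_variance_fraction": float(varfrac[0]),
        "index_heritability_by_mother": h2,
        "distance_regressions": regressions,
    }
    write_results(payload, RUN / "morpho.json", AnalysisConfig(), SEED)
    print(f"wrote {RUN / 'morpho.json'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
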