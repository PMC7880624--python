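#!/usr/bin/env python
"""PCA + linear-SVM separability of simulated two-class cohorts.

Three experiments, 15 measurements per class at SNR 10^3, features =
amplitude-ratio spectra A_sam/A_ref over 0.2-1.4 THz, PCA to 2 scores, then
a linear SVM (C = 1.0):

1. fixed pellet geometry, 10% contrast imposed on the density-normalized
   refractive index -> the classes separate (training accuracy 1.0,
   permutation p ~ 0.005): the contrast leaves a coherent ~1.3% Fresnel
   signature across the band.
2. fixed geometry, zero contrast -> accuracy compatible with chance
   (permutation p >> 0.05): the pipeline does not invent structure.
3. the same 10% contrast with geometry drawn from the full measured ranges
   (thickness 0.52-1.81 mm, density 1.000-1.358 mg/mm^3) -> NOT separable:
   amplitude-ratio features scale as exp(-alpha d/2), so pellet-to-pellet
   alpha*d spread dominates the index signature.  This is the classification
   analogue of why optical properties must be density-normalized before
   pellets can be compared.
"""

from pathlib import Path

import numpy as np

from thzpellet import CohortSpec, NoiseSpec, classify_pipeline, simulate_cohort
from thzpellet.extraction import ExtractionConfig, pair_spectra

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

SEED = 7


def run(label: str, spec: CohortSpec, rows: list[str]) -> None:
    pairs = simulate_cohort(spec, NoiseSpec(1e3, seed=SEED))
    config = ExtractionConfig()
    spectra = [pair_spectra(p, config) for p in pairs]
    labels = [p.geometry.class_label for p in pairs]
    rep = classify_pipeline(spectra, labels, n_permutations=199, seed=SEED)
    evr = rep.pca.explained_variance_ratio
    print(
        f"{label}: accuracy {rep.svm.training_accuracy:.3f} "
        f"separable={rep.separable} perm_p={rep.permutation_p:.3f} "
        f"PC1/PC2 variance {evr[0]:.3f}/{evr[1]:.3f} "
        f"informative f {rep.informative_frequencies[0]:.2f}/"
        f"{rep.informative_frequencies[1]:.2f} THz"
    )
    rows.append(
        f"{label}\t{rep.svm.training_accuracy:.4f}\t{rep.permutation_p:.4f}"
        f"\t{evr[0]:.4f}\t{evr[1]:.4f}"
    )


def main() -> None:
    rows = ["experiment\ttraining_accuracy\tpermutation_p\tpc1_evr\tpc2_evr"]
    fixed = dict(thickness_range=(1.1, 1.1), density_range=(1.1, 1.1))
    run("fixed-geometry, 10% contrast", CohortSpec(contrast=0.10, **fixed), rows)
    run("fixed-geometry, 0% contrast", CohortSpec(contrast=0.0, **fixed), rows)
    run("full-geometry-spread, 10% contrast", CohortSpec(contrast=0.10), rows)
    (RESULTS / "classification.tsv").write_text("\n".join(rows) + "\n")
    print(f"wrote {RESULTS / 'classification.tsv'}")


if __name__ == "__main__":
    main()
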