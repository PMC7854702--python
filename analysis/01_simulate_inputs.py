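#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes, under results/inputs/:
  - a five-point dilution series (0.5-4.0 mg/mL) of scattering profiles
    with planted M_W, A2, Rg0, B_if;
  - Pr / Pfr / photosteady-state absorption spectra (planted Pfr fraction
    0.61);
  - component and photosteady-state scattering profiles (planted Pr-Pr
    population 0.39);
  - a 560-model, three-family bead-model ensemble with truth labels;
  - a two-domain Calpha structure whose B-factors derive from an elastic
    network with a 9 A cutoff.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from phytosaxs import bead_models as bm
from phytosaxs import enm_nma as enm
from phytosaxs import saxs_core as sc
from phytosaxs import synthetic_data as sd

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"

TRUTH = {
    "mw_kda": 250.0, "a2": 1e-4, "b_if": 5.0,
    "pr_rg0_A": 57.1, "pfr_rg0_A": 62.6,
    "w_prpr": 0.39, "fraction_pfr": 0.61,
    "planted_cutoff_A": 9.0,
    "seed": SEED,
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # dilution series for the Pr form
    shape_pr = bm.generate_shape("sphere", {"radius": TRUTH["pr_rg0_A"] / np.sqrt(0.6)},
                                 800, seed=SEED)
    for prof in sd.make_dilution_series(shape_pr, mw=TRUTH["mw_kda"],
                                        a2=TRUTH["a2"], b_if=TRUTH["b_if"],
                                        rg0=TRUTH["pr_rg0_A"], seed=SEED):
        sc.write_profile(prof, OUT / f"pr_C{prof.concentration:g}.dat")

    # absorption spectra
    pr, pfr, steady = sd.make_spectra(fraction_pfr=TRUTH["fraction_pfr"],
                                      noise=1e-4, seed=SEED)
    for spec, name in ((pr, "spec_pr"), (pfr, "spec_pfr"), (steady, "spec_steady")):
        pd.DataFrame({"wavelength_nm": spec.wavelength,
                      "absorbance": spec.absorbance}).to_csv(
            OUT / f"{name}.csv", index=False)

    # photosteady-state scattering mixture
    s = np.linspace(1e-3, 0.12, 240)
    i_pr = bm.debye_intensity(
        bm.generate_shape("sphere", {"radius": 30.0}, 600, seed=SEED + 1), s)
    i_pfr = bm.debye_intensity(
        bm.generate_shape("sphere", {"radius": 35.0}, 600, seed=SEED + 2), s)
    mix = sd.make_steady_mixture(i_pr, i_pfr, w_prpr=TRUTH["w_prpr"])
    for prof, name in ((i_pr, "saxs_pr"), (i_pfr, "saxs_pfr_truth"),
                       (mix, "saxs_steady")):
        sc.write_profile(prof, OUT / f"{name}.dat")

    # bead-model ensemble (PDBs are bulky: keep truth labels + regenerate)
    models, truth = sd.make_model_ensemble(n_per_family=[178, 177, 177],
                                           jitter_sigma=2.0,
                                           outlier_fraction=0.05, seed=SEED)
    np.savetxt(OUT / "ensemble_truth_labels.csv", truth, fmt="%d",
               header="family (-1 = outlier)")
    print(f"ensemble: {len(models)} models in 3 families "
          f"({(truth == -1).sum()} outliers); regenerate with seed {SEED}")

    # elastic-network structure
    st = sd.make_enm_structure(planted_cutoff=TRUTH["planted_cutoff_A"],
                               noise=0.05, seed=SEED)
    enm.write_mode_pdb(st, np.zeros_like(st.coords), OUT / "enm_structure.pdb",
                       single_model=True)

    with open(OUT / "truth.json", "w") as fh:
        json.dump(TRUTH, fh, indent=2)
    print(f"wrote synthetic inputs to {OUT}")


if __name__ == "__main__":
    main()
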