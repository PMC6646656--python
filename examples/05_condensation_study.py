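"""Chromatin condensation and the energy imparted to the chromatin.

Simulates a population of AB cells spanning five mitotic chromatin
arrangements, each irradiated with 10^3 protons. The chromatin's share of
the nuclear energy rises from a few percent (diffuse interphase/prophase
chromatin, mostly off the beam axis) to about half for the compact
metaphase plate sitting on the axis.
"""

import embryodose as ed

cells, summary = ed.run_condensation_study(
    ed.StudyConfig(population_size=40, n_protons=1000, seed=1))

print(cells.groupby("state")[["chromatin_pj", "nuclear_pj",
                              "fraction_pct"]].mean().round(2).to_string())
print(f"\nnuclear energy: {summary['nuclear_mean_pj']:.1f} ± "
      f"{summary['nuclear_sd_pj']:.1f} pJ per 10^3 protons "
      f"(CV {summary['nuclear_cv_pct']:.0f}% — tracks the ~25% spread of "
      "the traversed nuclear thickness, 6 ± 1.5 µm)")
print(f"prophase chromatin deposit: "
      f"{summary['prophase_chromatin_mean_pj']:.2f} ± "
      f"{summary['prophase_chromatin_sd_pj']:.2f} pJ — timing jitter within "
      "prophase barely changes the chromatin dose")
print(f"metaphase chromatin share: "
      f"{summary['per_state']['metaphase']['fraction_mean_pct']:.0f}% of the "
      "nuclear energy, vs "
      f"{summary['prophase_fraction_mean_pct']:.1f}% in prophase")
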