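"""Spearman correlation network between spectral markers and clinical labs.

Builds the network the way exploratory biomarker studies do: every
marker-marker and marker-covariate pair is rank-correlated, and edges with
p < 0.05 (raw) are kept.  Covariates are drawn independently given outcome
by the generator, so marker-covariate edges here arise through the shared
outcome only — expect fewer and weaker edges than between neighbouring
spectral variables.
"""

from dataclasses import replace

from mirspec import (
    CohortConfig,
    calibrate_effect,
    preprocess_set,
    simulate_cohort,
    spearman_network,
)

base = CohortConfig(seed=42)
scale = calibrate_effect(0.90, base, pilot_n=2000)
spectra, cohort, truth = simulate_cohort(replace(base, effect_scale=scale))
proc = preprocess_set(spectra)
X = proc.select_wavenumbers(truth.informative_wavenumbers)

edges = spearman_network(X, cohort, spectral_names=truth.informative_wavenumbers)
spectral = {f"{w:g}" for w in truth.informative_wavenumbers}
ss = [e for e in edges if e.node_a in spectral and e.node_b in spectral]
sc = [e for e in edges if (e.node_a in spectral) != (e.node_b in spectral)]

print(f"{len(edges)} significant edges: {len(ss)} marker-marker, {len(sc)} marker-clinical")
print("\nstrongest edges (|r| descending):")
for e in sorted(edges, key=lambda e: -abs(e.r))[:10]:
    kind = "spec-spec" if e.node_a in spectral and e.node_b in spectral else "spec-clin"
    print(f"  {e.node_a:>10} -- {e.node_b:<16} r = {e.r:+.2f}  p = {e.p:.2e}  ({kind})")
print("\npositive r: the two quantities rise together across patients; "
      "negative r: one rises as the other falls")
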