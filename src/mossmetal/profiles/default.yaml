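# Default synthetic-survey profile, version 1.
#
# Emulates a nine-site urban biomonitoring survey: one pleurocarpous moss,
# two evergreen tree-leaf species and surface soil, 12 trace metals plus the
# crust-conservative reference element Al, three replicates per sample.
# Baseline concentrations are the published per-medium survey means
# (µg g⁻¹ dry weight); the moss baseline is the leaf_a baseline times the
# published per-element moss/leaf_a accumulation ratio.  Two latent
# anthropogenic source factors with disjoint element sets drive the
# site-to-site variation on the log10 scale: "traffic" (strongest at the
# roadside sites TR, GS) and "industry" (strongest at the industrial sites
# WS, WB); the background campus site HZ has zero source score.  Mn and Co
# are soil-coupled: their traffic signal reaches the plants through the
# surface soil (soil_loading on the factor, inherited by plants with
# coefficient beta), so their plant concentrations track soil.
name: default
version: 1
design:
  sites: [HZ, HX, JX, LY, MA, TR, GS, WS, WB]
  background_site: HZ
  n_replicates: 3
  media:
    moss: "Haplocladium angustifolium"
    leaf_a: "Cinnamomum bodinieri"
    leaf_b: "Osmanthus fragrans"
    soil: "surface soil"
  reference_element: Al
model:
  baseline:   # µg/g dry weight, raw scale
    leaf_a: {Ag: 0.008, As: 0.317, Cd: 0.050, Co: 0.108, Cr: 0.579, Cu: 5.23,
             Mn: 120.0, Mo: 41.1, Ni: 0.549, Pb: 2.361, V: 0.735, Zn: 13.4, Al: 150.0}
    leaf_b: {Ag: 0.009, As: 0.196, Cd: 0.182, Co: 0.224, Cr: 0.538, Cu: 5.14,
             Mn: 107.0, Mo: 144.0, Ni: 0.562, Pb: 3.59, V: 0.575, Zn: 27.1, Al: 150.0}
    soil:   {Ag: 0.107, As: 22.7, Cd: 0.185, Co: 16.4, Cr: 49.3, Cu: 28.0,
             Mn: 667.0, Mo: 387.0, Ni: 18.4, Pb: 32.7, V: 124.0, Zn: 67.8, Al: 70000.0}
  # moss baseline = leaf_a baseline × multiplier (dimensionless, >1)
  moss_multiplier: {Ag: 19.8, As: 17.4, Cd: 15.3, Co: 51.3, Cr: 29.9, Cu: 5.17,
                    Mn: 4.08, Mo: 10.4, Ni: 10.3, Pb: 13.6, V: 48.5, Zn: 9.38, Al: 20.0}
  factors:
    traffic:
      loadings: {Cu: 0.45, Pb: 0.45, As: 0.45, Ag: 0.45, Mo: 0.45, Cd: 0.35, Zn: 0.35}
      site_scores: {HZ: 0.0, HX: 0.765, JX: 0.51, LY: 0.34, MA: 0.595,
                    TR: 2.89, GS: 3.4, WS: 0.935, WB: 0.68}
    industry:
      loadings: {V: 0.45, Cr: 0.45, Ni: 0.45}
      site_scores: {HZ: 0.0, HX: 0.51, JX: 0.34, LY: 0.425, MA: 0.51,
                    TR: 0.765, GS: 0.935, WS: 2.72, WB: 3.23}
  soil_coupling:
    Mn: {beta: 1.0, factor: traffic, soil_loading: 0.45}
    Co: {beta: 1.0, factor: traffic, soil_loading: 0.35}
  noise:   # standard deviations on the log10 scale
    sigma_site: 0.05
    sigma_replicate: 0.02
    sigma_soil: 0.12
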