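# Urinary-nitrogen prediction equations, exactly as published (rounded
# coefficients are canonical; refitted coefficients live in separate
# CoefficientSets and are never substituted here).
#
# response: un_gd      -> UN (g/d)
#           un_per_bw  -> UN (g/d) per kg BW; predictions are multiplied
#                         through by BW to return g/d.
# terms keys: intercept, mun (mg/dL), cp (% of DM), dmi (kg/d), bw (kg)
# diet_terms: coefficients that differ between the TMR and PASTURE strata.
# se / diet_se: standard errors of the parameters, where published.

EQ1:
  description: "UN = 12.54 x MUN (TMR digestibility/N-balance trials)"
  response: un_gd
  terms: {mun: 12.54}

EQ2:
  description: "UN/BW = 0.0259 x MUN (Latin-square TMR trial)"
  response: un_per_bw
  terms: {mun: 0.0259}

EQ3:
  description: "UN = -148.8 + 8.06 x MUN + 8.91 x CP + 4.06 x DMI (northwestern-Europe meta-analysis coefficients)"
  response: un_gd
  terms: {intercept: -148.8, mun: 8.06, cp: 8.91, dmi: 4.06}

EQ4:
  description: "UN/BW = 0.0214 x MUN (TMR) / 0.0240 x MUN (pasture)"
  response: un_per_bw
  diet_terms:
    TMR: {mun: 0.0214}
    PASTURE: {mun: 0.0240}
  diet_se:
    TMR: {mun: 0.00156}
    PASTURE: {mun: 0.000704}

EQ5:
  description: "UN = -209.4 + 6.8 x MUN + 12.4 x CP + 4.8 x DMI"
  response: un_gd
  terms: {intercept: -209.4, mun: 6.8, cp: 12.4, dmi: 4.8}
  se: {intercept: 24.40, mun: 0.80, cp: 1.51, dmi: 0.74}

EQ6:
  description: "UN = -281.3 + 6.7 x MUN + 13.2 x CP + 2.8 x DMI + 0.16 x BW"
  response: un_gd
  terms: {intercept: -281.3, mun: 6.7, cp: 13.2, dmi: 2.8, bw: 0.16}
  se: {intercept: 31.04, mun: 0.77, cp: 1.47, dmi: 0.93, bw: 0.046}

EQ7:
  description: "UN = (-0.253 + 0.00932 x MUN + 0.0260 x CP) x BW"
  response: un_per_bw
  terms: {intercept: -0.253, mun: 0.00932, cp: 0.0260}
  se: {intercept: 0.0323, mun: 0.00132, cp: 0.00250}
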