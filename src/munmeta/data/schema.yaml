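# Canonical input-table schema for munmeta treatment-mean tables.
# Delimited text (comma or tab), UTF-8, one header row, one row per
# treatment mean.  Map your own column names onto the canonical names
# with a {canonical: source_column} mapping (CLI: --column-map).
columns:
  study_id:       {unit: "-",       required: true,  description: "study identifier (DOI string); one diet type per study"}
  diet:           {unit: "-",       required: true,  description: "TMR or PASTURE (fresh forage accepted as alias)"}
  un_gd:          {unit: "g/d",     required: true,  description: "observed urinary nitrogen excretion (> 0)"}
  un_sem:         {unit: "g/d",     required: false, description: "standard error of the treatment-mean UN; required (> 0) for weighted analyses"}
  mun_mgdl:       {unit: "mg/dL",   required: true,  description: "milk urea nitrogen (> 0)"}
  bw_kg:          {unit: "kg",      required: true,  description: "body weight (> 0)"}
  dmi_kg:         {unit: "kg/d",    required: true,  description: "dry matter intake (> 0)"}
  cp_pct:         {unit: "% of DM", required: true,  description: "dietary crude protein, 0-100 exclusive"}
  ndf_pct:        {unit: "% of DM", required: false, description: "dietary neutral detergent fiber"}
  n_intake_gd:    {unit: "g/d",     required: false, description: "nitrogen intake"}
  milk_yield_kgd: {unit: "kg/d",    required: false, description: "milk yield"}
  dim_d:          {unit: "d",       required: false, description: "days in milk"}
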