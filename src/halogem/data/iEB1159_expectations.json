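{
  "note": "Validation battery configuration for the iEB1159 model of Chromohalobacter canadensis 85B (BioModels MODEL2204110001). Running it requires downloading that SBML file; nothing here is bundled with the package. The medium lists glucose at the standard 10 mmol/gDW/h carbon uptake with inorganic nutrients effectively unconstrained; exchange identifiers follow BiGG conventions and may need adjusting to the deposited file. Carbon-source expectations encode the published growth (+), no-growth (-) and not-in-model calls per compound.",
  "medium": {
    "EX_glc__D_e": 10,
    "EX_o2_e": 1000,
    "EX_nh4_e": 1000,
    "EX_pi_e": 1000,
    "EX_so4_e": 1000,
    "EX_h2o_e": 1000,
    "EX_h_e": 1000,
    "EX_k_e": 1000,
    "EX_na1_e": 1000,
    "EX_cl_e": 1000,
    "EX_mg2_e": 1000,
    "EX_ca2_e": 1000,
    "EX_fe2_e": 1000,
    "EX_fe3_e": 1000,
    "EX_mn2_e": 1000,
    "EX_zn2_e": 1000,
    "EX_cu2_e": 1000,
    "EX_cobalt2_e": 1000,
    "EX_mobd_e": 1000,
    "EX_ni2_e": 1000
  },
  "carbon_source": "EX_glc__D_e",
  "carbon_uptake": 10,
  "oxygen_exchange": "EX_o2_e",
  "expectations": {
    "gene_count": 1159,
    "blocked_metabolite_count": 37,
    "essential_gene_count": 60,
    "anaerobic_no_growth": true,
    "electron_acceptors": ["EX_no3_e", "EX_fe3_e"],
    "carbon_sources": {
      "EX_glc__D_e": "grows",
      "EX_malt_e": "grows",
      "EX_malttr_e": "grows",
      "EX_arab__D_e": "grows",
      "EX_cellb_e": "grows",
      "EX_fru_e": "grows",
      "EX_gal_e": "grows",
      "EX_gal_bD_e": "grows",
      "EX_glcn_e": "grows",
      "EX_malthp_e": "grows",
      "EX_malthx_e": "grows",
      "EX_maltpt_e": "grows",
      "EX_malttt_e": "grows",
      "EX_man_e": "grows",
      "EX_mnl_e": "grows",
      "EX_raffin_e": "grows",
      "EX_rib__D_e": "grows",
      "EX_sbt__D_e": "grows",
      "EX_sucr_e": "grows",
      "EX_tre_e": "grows",
      "EX_xyl__D_e": "grows",
      "EX_14glucan_e": "grows",
      "EX_2dhglcn_e": "grows",
      "EX_adn_e": "grows",
      "EX_cytd_e": "grows",
      "EX_uri_e": "grows",
      "EX_salcn_e": "grows",
      "EX_rmn_e": "does_not_grow",
      "EX_cit_e": "does_not_grow",
      "EX_fum_e": "does_not_grow",
      "EX_lys__L_e": "does_not_grow",
      "EX_lcts_e": "does_not_grow",
      "EX_esculin_e": "not_in_model",
      "EX_starch_e": "not_in_model",
      "EX_rbt_e": "not_in_model"
    },
    "production": [
      {"metabolite": "phb_c", "maximum": 12.35, "growth_requirement": 0.0},
      {"metabolite": "ectoine_c", "maximum": 7.05, "growth_requirement": 0.0}
    ]
  }
}
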