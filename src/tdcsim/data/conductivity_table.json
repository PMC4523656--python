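{
  "version": "1.0",
  "units": "S/m",
  "entries": [
    {"canonical_label": "air", "aliases": ["internal_air", "pharynx", "trachea_lumen"], "sigma_S_per_m": 0.0, "source": "Table 2"},
    {"canonical_label": "adrenal_gland", "aliases": ["epididymis", "hypophysis", "pancreas", "stomach", "stomach_lumen", "small_intestine", "small_intestine_lumen", "thymus", "thyroid_gland", "esophagus", "esophagus_lumen"], "sigma_S_per_m": 0.51113, "source": "Table 2"},
    {"canonical_label": "blood", "aliases": ["artery", "vein", "blood_vessel", "heart_lumen", "penis"], "sigma_S_per_m": 0.7, "source": "Table 2"},
    {"canonical_label": "bladder", "aliases": [], "sigma_S_per_m": 0.202783, "source": "Table 2"},
    {"canonical_label": "bone", "aliases": ["mandible", "marrow_red", "patella", "skull", "teeth", "vertebrae"], "sigma_S_per_m": 0.020028, "source": "Table 2"},
    {"canonical_label": "brain_grey_matter", "aliases": ["grey_matter", "hippocampus", "hypothalamus", "pineal_body", "thalamus"], "sigma_S_per_m": 0.027512, "source": "Table 2"},
    {"canonical_label": "brain_white_matter", "aliases": ["white_matter", "anterior_commissura", "posterior_commissura"], "sigma_S_per_m": 0.027656, "source": "Table 2"},
    {"canonical_label": "breast", "aliases": [], "sigma_S_per_m": 0.2617535, "source": "Table 2"},
    {"canonical_label": "bronchi", "aliases": ["bronchi_lumen", "ureter_urethra"], "sigma_S_per_m": 0.25055, "source": "Table 2"},
    {"canonical_label": "cartilage", "aliases": ["ear_cartilage", "intervertebral_disk", "larynx", "meniscus", "trachea"], "sigma_S_per_m": 0.16113, "source": "Table 2"},
    {"canonical_label": "cerebellum", "aliases": [], "sigma_S_per_m": 0.047512, "source": "Table 2"},
    {"canonical_label": "cerebrospinal_fluid", "aliases": ["csf"], "sigma_S_per_m": 2.0, "source": "Table 2"},
    {"canonical_label": "connective_tissue", "aliases": [], "sigma_S_per_m": 0.1215635, "source": "Table 2"},
    {"canonical_label": "cornea", "aliases": [], "sigma_S_per_m": 0.4113, "source": "Table 2"},
    {"canonical_label": "muscle", "aliases": ["diaphragm"], "sigma_S_per_m": 0.201967, "source": "Table 2"},
    {"canonical_label": "skin", "aliases": ["ear_skin", "scalp"], "sigma_S_per_m": 0.012147, "source": "Table 2"},
    {"canonical_label": "eye_lens", "aliases": ["ovary"], "sigma_S_per_m": 0.3113, "source": "Table 2"},
    {"canonical_label": "eye_sclera", "aliases": [], "sigma_S_per_m": 0.501392, "source": "Table 2"},
    {"canonical_label": "eye_vitreous_humor", "aliases": [], "sigma_S_per_m": 1.5, "source": "Table 2"},
    {"canonical_label": "fat_sat", "aliases": ["fat", "subcutaneous_adipose_tissue"], "sigma_S_per_m": 0.012207, "source": "Table 2"},
    {"canonical_label": "gallbladder", "aliases": [], "sigma_S_per_m": 0.9, "source": "Table 2"},
    {"canonical_label": "heart_muscle", "aliases": [], "sigma_S_per_m": 0.053677, "source": "Table 2"},
    {"canonical_label": "kidney_cortex", "aliases": ["kidney_medulla"], "sigma_S_per_m": 0.0544105, "source": "Table 2"},
    {"canonical_label": "large_intestine", "aliases": ["large_intestine_lumen", "vagina"], "sigma_S_per_m": 0.0122052, "source": "Table 2"},
    {"canonical_label": "liver", "aliases": [], "sigma_S_per_m": 0.027714, "source": "Table 2"},
    {"canonical_label": "lung", "aliases": [], "sigma_S_per_m": 0.120847, "source": "Table 2"},
    {"canonical_label": "medulla_oblongata", "aliases": ["midbrain", "pons", "brainstem"], "sigma_S_per_m": 0.027584, "source": "Table 2"},
    {"canonical_label": "mucosa", "aliases": [], "sigma_S_per_m": 0.0004, "source": "Table 2"},
    {"canonical_label": "nerve", "aliases": ["spinal_cord"], "sigma_S_per_m": 0.017126, "source": "Table 2"},
    {"canonical_label": "prostate", "aliases": ["testis"], "sigma_S_per_m": 0.41113, "source": "Table 2"},
    {"canonical_label": "spleen", "aliases": [], "sigma_S_per_m": 0.0395962, "source": "Table 2"},
    {"canonical_label": "tendon_ligament", "aliases": [], "sigma_S_per_m": 0.250922, "source": "Table 2"},
    {"canonical_label": "tongue", "aliases": [], "sigma_S_per_m": 0.26113, "source": "Table 2"},
    {"canonical_label": "uterus", "aliases": [], "sigma_S_per_m": 0.201296, "source": "Table 2"},
    {"canonical_label": "electrode_pad", "aliases": [], "sigma_S_per_m": 59000000.0, "source": "electrode model"},
    {"canonical_label": "sponge", "aliases": [], "sigma_S_per_m": 0.3, "source": "electrode model"}
  ]
}
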