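{
  "boxed_warning": ["boxed warning", "warning:"],
  "indication": ["indications and usage"],
  "dosage_admin": ["dosage and administration"],
  "pregnancy": ["pregnancy"],
  "lactation": ["lactation", "nursing mothers"],
  "mechanism_of_action": ["mechanism of action"],
  "pharmacodynamics": ["pharmacodynamics"],
  "pharmacokinetics": ["pharmacokinetics"],
  "absorption": ["absorption"],
  "distribution": ["distribution"],
  "metabolism": ["metabolism"],
  "excretion": ["excretion", "elimination"],
  "food_effect": ["food effect", "food effects", "effect of food", "effects of food"]
}
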