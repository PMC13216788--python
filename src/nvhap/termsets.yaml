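# Bundled default term sets for the radiology-report exclusion rule.
# Both sets are RECONSTRUCTIONS assembled from the published rule sketch
# ("no" + "infiltrate" in one sentence, restricting terms such as "but" or
# "left"); the original hospital lists are unpublished.  Hospitals should
# curate and configure their own lists.  Terms are lowercase; matching
# folds diacritics, so accented and unaccented spellings match either way.
de:
  language_tag: de
  negation_terms: ["no", "kein", "keine", "keinen", "keinem", "keiner", "nicht", "ohne"]
  infiltrate_terms: ["infiltrate", "infiltrates", "infiltrat", "infiltraten", "infiltrats"]
  restricting_terms: ["but", "left", "aber", "jedoch", "links", "ausser"]
fr:
  language_tag: fr
  negation_terms: ["pas", "sans", "aucun", "aucune", "non", "absence"]
  infiltrate_terms: ["infiltrat", "infiltrats", "infiltration", "infiltrations"]
  restricting_terms: ["mais", "gauche", "sauf", "cependant", "toutefois"]
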