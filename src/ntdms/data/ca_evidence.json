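{
 "chain_length": 161,
 "note": "CAD evidence-ion sets bracketing the three Ca2+ binding regions of human cardiac TnC (full UniProt numbering). The 0-Ca assignment of b65 in the domain-II set is implicit in the source data and flagged as an assumption.",
 "sets": {
  "domain_II": {
   "isolation_mz": 2321,
   "total_adducts": 3,
   "assumed_zero_adducts": ["b65"],
   "ions": [
    {"series": "b", "index": 65, "adduct_count": 0},
    {"series": "b", "index": 91, "adduct_count": 1},
    {"series": "y", "index": 85, "adduct_count": 2},
    {"series": "y", "index": 94, "adduct_count": 3}
   ]
  },
  "domain_III": {
   "isolation_mz": 2312,
   "total_adducts": 1,
   "ions": [
    {"series": "b", "index": 109, "adduct_count": 0},
    {"series": "b", "index": 115, "adduct_count": 1},
    {"series": "y", "index": 30, "adduct_count": 0},
    {"series": "y", "index": 52, "adduct_count": 1}
   ]
  },
  "domain_IV": {
   "isolation_mz": 2316,
   "total_adducts": 2,
   "ions": [
    {"series": "b", "index": 140, "adduct_count": 1},
    {"series": "b", "index": 145, "adduct_count": 2},
    {"series": "y", "index": 16, "adduct_count": 0},
    {"series": "y", "index": 22, "adduct_count": 1}
   ]
  }
 },
 "binding_order": ["domain_III", "domain_IV", "domain_II"]
}
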