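{
  "comment": "Events whose placement rests on outside evidence (gene trees including whole-genome-assembly species and earlier comparative studies of the family), not derivable from the captured-species status matrix alone.",
  "events": [
    {"branch_id": "1", "type": "birth", "gene": "TAS2R10-2",
     "note": "TAS2R10 duplication at the cercopithecid ancestor; gene-tree evidence"},
    {"branch_id": "1", "type": "birth", "gene": "TAS2R413-2",
     "note": "TAS2R413 duplication at the cercopithecid ancestor; gene-tree evidence"},
    {"branch_id": "1", "type": "birth", "gene": "TAS2R418",
     "note": "arose within the TAS2R405 group at the cercopithecid ancestor; disrupted copies in database colobines polarize the birth above the crown split"},
    {"branch_id": "1", "type": "birth", "gene": "TAS2R404",
     "note": "TAS2R409-derived duplication giving rise to TAS2R403 and TAS2R404; earlier comparative study"},
    {"branch_id": "1", "type": "disruption", "gene": "TAS2R15",
     "note": "pseudogenized at the cercopithecid ancestor; earlier comparative study"}
  ]
}
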