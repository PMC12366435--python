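{
 "description": "Printed bootstrap moments (mean, SD) and two-sided p-values for the 46 lexicogrammatical items significant at p < 0.05, as published for the 64-ASD / 71-non-ASD interview corpus.",
 "rows": [
  {
   "lexicogrammar": "Auxiliary verbs-benefactive do (for someone)",
   "mean": -0.0052,
   "sd": 0.0018,
   "p_value": 0.0031
  },
  {
   "lexicogrammar": "Auxiliary verbs-stative-do (end up/ended up, implying regret/vexation)",
   "mean": -0.0183,
   "sd": 0.0075,
   "p_value": 0.0148
  },
  {
   "lexicogrammar": "Auxiliary verbs-stative-try (doing/to do something and observe outcome)",
   "mean": -0.007,
   "sd": 0.0032,
   "p_value": 0.0256
  },
  {
   "lexicogrammar": "Clause complexes-noun clauses",
   "mean": -0.0503,
   "sd": 0.0201,
   "p_value": 0.0124
  },
  {
   "lexicogrammar": "Clause complexes-reported clauses",
   "mean": -0.0741,
   "sd": 0.0214,
   "p_value": 0.0005
  },
  {
   "lexicogrammar": "Clause complexes-adnominal clauses",
   "mean": -0.0512,
   "sd": 0.0177,
   "p_value": 0.0038
  },
  {
   "lexicogrammar": "Clause complexes/Te-form conjunctive clauses (parallel/contrast)",
   "mean": -0.0247,
   "sd": 0.0069,
   "p_value": 0.0004
  },
  {
   "lexicogrammar": "Clause complexes/Te-form/conjunctive clauses-forerunner",
   "mean": -0.0074,
   "sd": 0.003,
   "p_value": 0.0136
  },
  {
   "lexicogrammar": "Clause complexes/Te-form/conjunctive clauses-cause/reason",
   "mean": -0.0411,
   "sd": 0.0103,
   "p_value": 0.0001
  },
  {
   "lexicogrammar": "Clause complexes/Te-form/conjunctive clauses-attendant circumstance",
   "mean": -0.0185,
   "sd": 0.0079,
   "p_value": 0.0181
  },
  {
   "lexicogrammar": "Clause complexes/Te-form/conjunctive clauses-sequence of actions",
   "mean": -0.0223,
   "sd": 0.0084,
   "p_value": 0.0079
  },
  {
   "lexicogrammar": "Clause complexes-parallel clauses",
   "mean": 0.0808,
   "sd": 0.0173,
   "p_value": 0.0
  },
  {
   "lexicogrammar": "Clause complexes-conditional clauses-cause/reason",
   "mean": -0.0381,
   "sd": 0.0151,
   "p_value": 0.0114
  },
  {
   "lexicogrammar": "Clause complexes-conditional clauses-resultative condition",
   "mean": -0.0227,
   "sd": 0.0111,
   "p_value": 0.041
  },
  {
   "lexicogrammar": "Logico-semantic relation/projection-embedding",
   "mean": -0.1052,
   "sd": 0.0286,
   "p_value": 0.0002
  },
  {
   "lexicogrammar": "Logico-semantic relation/projection-idea",
   "mean": -0.0683,
   "sd": 0.0191,
   "p_value": 0.0003
  },
  {
   "lexicogrammar": "Logico-semantic relation/expansion-enhancement-manner",
   "mean": -0.0196,
   "sd": 0.0083,
   "p_value": 0.0181
  },
  {
   "lexicogrammar": "Logico-semantic relation/expansion-enhancement-cause-conditional",
   "mean": -0.107,
   "sd": 0.025,
   "p_value": 0.0
  },
  {
   "lexicogrammar": "Logico-semantic relation/expansion-extension-additive",
   "mean": -0.086,
   "sd": 0.0221,
   "p_value": 0.0001
  },
  {
   "lexicogrammar": "Logico-semantic relation/expansion-elaboration-exemplifying",
   "mean": 0.0833,
   "sd": 0.0172,
   "p_value": 0.0
  },
  {
   "lexicogrammar": "Process type/existential",
   "mean": 0.1336,
   "sd": 0.0292,
   "p_value": 0.0
  },
  {
   "lexicogrammar": "Process type/relational-attribute",
   "mean": -0.0849,
   "sd": 0.0316,
   "p_value": 0.0072
  },
  {
   "lexicogrammar": "Appraisal/attitude/judgment-propriety",
   "mean": -0.0096,
   "sd": 0.0042,
   "p_value": 0.0235
  },
  {
   "lexicogrammar": "Appraisal/attitude/judgment-veracity",
   "mean": -0.0124,
   "sd": 0.0052,
   "p_value": 0.0163
  },
  {
   "lexicogrammar": "Appraisal/attitude/affect-satisfaction",
   "mean": -0.0328,
   "sd": 0.0049,
   "p_value": 0.0
  },
  {
   "lexicogrammar": "Appraisal/attitude/appreciation-phase-space",
   "mean": -0.0024,
   "sd": 0.0011,
   "p_value": 0.0236
  },
  {
   "lexicogrammar": "Appraisal/attitude/appreciation-reaction",
   "mean": -0.0533,
   "sd": 0.0206,
   "p_value": 0.0098
  },
  {
   "lexicogrammar": "Appraisal/graduation/force-intensification",
   "mean": -0.1595,
   "sd": 0.021,
   "p_value": 0.0
  },
  {
   "lexicogrammar": "Appraisal/graduation/force-quantification",
   "mean": -0.0122,
   "sd": 0.0057,
   "p_value": 0.0333
  },
  {
   "lexicogrammar": "Evidentiality/appearance",
   "mean": -0.0094,
   "sd": 0.0041,
   "p_value": 0.0225
  },
  {
   "lexicogrammar": "Modality/modalization/modal adjunct/probability",
   "mean": -0.0201,
   "sd": 0.0064,
   "p_value": 0.0016
  },
  {
   "lexicogrammar": "Modality/modalization/probability",
   "mean": -0.0345,
   "sd": 0.0169,
   "p_value": 0.041
  },
  {
   "lexicogrammar": "Modality/modulation/obligation",
   "mean": -0.0042,
   "sd": 0.0015,
   "p_value": 0.0047
  },
  {
   "lexicogrammar": "Negotiating particles-sentence-final:kane",
   "mean": -0.0334,
   "sd": 0.0103,
   "p_value": 0.0012
  },
  {
   "lexicogrammar": "Negotiating particles-sentence-final:ne",
   "mean": -0.129,
   "sd": 0.0281,
   "p_value": 0.0
  },
  {
   "lexicogrammar": "Negotiating particles-sentence-final:yo",
   "mean": -0.0329,
   "sd": 0.0081,
   "p_value": 0.0
  },
  {
   "lexicogrammar": "Negotiating particles-sentence-final:yone",
   "mean": -0.0146,
   "sd": 0.0042,
   "p_value": 0.0005
  },
  {
   "lexicogrammar": "Negotiating particles-mid sentence:kane",
   "mean": -0.0023,
   "sd": 0.0009,
   "p_value": 0.0072
  },
  {
   "lexicogrammar": "Negotiating particles-mid sentence:ne",
   "mean": -0.0363,
   "sd": 0.0102,
   "p_value": 0.0004
  },
  {
   "lexicogrammar": "Mood/explanatory mood:kedo",
   "mean": -0.0347,
   "sd": 0.0137,
   "p_value": 0.0111
  },
  {
   "lexicogrammar": "Mood/explanatory mood:ne",
   "mean": -0.0022,
   "sd": 0.001,
   "p_value": 0.0199
  },
  {
   "lexicogrammar": "Mood/explanatory mood:yo",
   "mean": -0.0259,
   "sd": 0.0063,
   "p_value": 0.0
  },
  {
   "lexicogrammar": "Mood/explanatory mood:yone",
   "mean": -0.0065,
   "sd": 0.0022,
   "p_value": 0.0041
  },
  {
   "lexicogrammar": "Filler/unto",
   "mean": 0.0354,
   "sd": 0.0135,
   "p_value": 0.0088
  },
  {
   "lexicogrammar": "Filler/kono",
   "mean": -0.0017,
   "sd": 0.0005,
   "p_value": 0.0021
  },
  {
   "lexicogrammar": "Onomatopoeia/imitative mimetic words",
   "mean": -0.0126,
   "sd": 0.0059,
   "p_value": 0.0315
  }
 ]
}
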