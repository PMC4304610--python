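# Toxicological reference points (mg/kg bw/day) used as MOE numerators,
# with health-based guidance values (ADI/MRL) retained for comparison only.
nicotine:
  value: 0.008
  endpoint_type: LOAEL
  endpoint_source: human
  secondary_value: 0.0008
  secondary_type: ADI
  reference: "EFSA; heart rate acceleration in humans"
glycerol:
  value: 10000
  endpoint_type: NOAEL
  endpoint_source: animal
  reference: "OECD SIDS; 2-year rat study, no effects observed"
1,2-propanediol:
  value: 2500
  endpoint_type: NOAEL
  endpoint_source: animal
  secondary_value: 25
  secondary_type: ADI
  reference: "JECFA; 2-year rat and dog studies"
ethylene glycol:
  value: 76
  endpoint_type: BMDL10
  endpoint_source: animal
  secondary_value: 0.8
  secondary_type: MRL
  reference: "ATSDR; developmental toxicity in mice"
1,3-propanediol:
  value: 1000
  endpoint_type: NOAEL
  endpoint_source: animal
  reference: "EFSA CONTAM; developmental toxicity study in rats"
thujone:
  value: 11
  endpoint_type: BMDL10
  endpoint_source: animal
  secondary_value: 0.11
  secondary_type: ADI
  reference: "clonic seizures in rats"
ethyl vanillin:
  value: 500
  endpoint_type: NOEL
  endpoint_source: animal
  secondary_value: 3
  secondary_type: ADI
  reference: "JECFA; 13-week rat study, no effects observed"
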