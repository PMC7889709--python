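# Age-specific pediatric SIRS thresholds transcribed from the 2005
# International Pediatric Sepsis Consensus Conference (IPSCC) table.
# The rule engine treats this file as data; edit a copy to change limits.
#
# Units: temperature degC, heart_rate /min, respiratory_rate /min,
# leukocyte_count 10^3/uL, immature_neutrophil_limit fraction of neutrophils.
# Limits are exclusive: a value must be strictly beyond the limit to fire.
# Bands are half-open [start_days, end_days) and partition 0 to 18 years.
version: ipscc-2005
comparator: exclusive
mandatory_criteria: [temperature, leukocytes]
immature_neutrophil_limit: 0.10
temperature:
  high: 38.5
  low: 36.0
age_bands:
  - name: 0d-1wk
    start_days: 0
    end_days: 7
    heart_rate: {high: 180, low: 100}
    respiratory_rate: {high: 50}
    leukocyte_count: {high: 34.0}
    bradycardia_applicable: true
  - name: 1wk-1mo
    start_days: 7
    end_days: 30
    heart_rate: {high: 180, low: 100}
    respiratory_rate: {high: 40}
    leukocyte_count: {high: 19.5, low: 5.0}
    bradycardia_applicable: true
  - name: 1mo-1yr
    start_days: 30
    end_days: 730
    heart_rate: {high: 180, low: 90}
    respiratory_rate: {high: 34}
    leukocyte_count: {high: 17.5, low: 5.0}
    bradycardia_applicable: true
  - name: 2-5yr
    start_days: 730
    end_days: 2190
    heart_rate: {high: 140}
    respiratory_rate: {high: 22}
    leukocyte_count: {high: 15.5, low: 6.0}
    bradycardia_applicable: false
  - name: 6-12yr
    start_days: 2190
    end_days: 4745
    heart_rate: {high: 130}
    respiratory_rate: {high: 18}
    leukocyte_count: {high: 13.5, low: 4.5}
    bradycardia_applicable: false
  - name: 13-18yr
    start_days: 4745
    end_days: 6570
    heart_rate: {high: 110}
    respiratory_rate: {high: 14}
    leukocyte_count: {high: 11.0, low: 4.5}
    bradycardia_applicable: false
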