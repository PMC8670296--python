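# Reference five-number summaries of per-gene percent methylation (%M, QM-MSP)
# for 13 candidate markers in a colon tissue training cohort:
# carcinoma n = 30, adjacent normal n = 23.
#
# Quartiles follow the rank k = p*(n+1) convention (Hyndman-Fan type 6).
# p_value is the two-sided Mann-Whitney carcinoma-vs-normal p; p_censored: true
# means the source reports it only as "< 0.0001" (stored here as 1e-4, an upper
# bound; any value below alpha = 0.05 behaves identically in the selection
# procedure).
#
# parse_ambiguous: true marks genes whose printed quartile rows carried
# transcription uncertainty; the values given are the unique parse satisfying
# min <= q25 <= median <= q75 <= max. Both such genes are removed by the
# significance filter on their p-values alone, so no downstream result
# depends on their quartiles.
cohort:
  n_carcinoma: 30
  n_normal: 23
genes:
  TMEFF2:
    carcinoma: {minimum: 0, q25: 40, median: 59, q75: 75, maximum: 94}
    normal:    {minimum: 0, q25: 0,  median: 1,  q75: 3,  maximum: 11}
    p_value: 1.0e-4
    p_censored: true
  GPX7:
    carcinoma: {minimum: 0, q25: 1,  median: 33, q75: 53, maximum: 72}
    normal:    {minimum: 0, q25: 0,  median: 0,  q75: 0,  maximum: 2}
    p_value: 1.0e-4
    p_censored: true
  MAL:
    carcinoma: {minimum: 9, q25: 21, median: 33, q75: 49, maximum: 71}
    normal:    {minimum: 0, q25: 1,  median: 2,  q75: 3,  maximum: 7}
    p_value: 1.0e-4
    p_censored: true
  ARHGEF7:
    carcinoma: {minimum: 0, q25: 0,  median: 8,  q75: 33, maximum: 75}
    normal:    {minimum: 0, q25: 0,  median: 0,  q75: 0,  maximum: 2}
    p_value: 1.0e-4
    p_censored: true
  TWIST1:
    carcinoma: {minimum: 6, q25: 14, median: 18, q75: 28, maximum: 50}
    normal:    {minimum: 1, q25: 3,  median: 4,  q75: 6,  maximum: 11}
    p_value: 1.0e-4
    p_censored: true
  AKR1B1:
    carcinoma: {minimum: 0, q25: 1,  median: 16, q75: 21, maximum: 52}
    normal:    {minimum: 0, q25: 0,  median: 0,  q75: 0,  maximum: 1}
    p_value: 1.0e-4
    p_censored: true
  HIN1:
    carcinoma: {minimum: 0, q25: 0,  median: 5,  q75: 18, maximum: 61}
    normal:    {minimum: 0, q25: 0,  median: 0,  q75: 0,  maximum: 0}
    p_value: 1.0e-4
    p_censored: true
  GAS7:
    carcinoma: {minimum: 0, q25: 6,  median: 9,  q75: 12, maximum: 36}
    normal:    {minimum: 0, q25: 0,  median: 1,  q75: 2,  maximum: 4}
    p_value: 1.0e-4
    p_censored: true
  TM6SF1:
    carcinoma: {minimum: 0, q25: 35, median: 47, q75: 58, maximum: 70}
    normal:    {minimum: 1, q25: 5,  median: 10, q75: 15, maximum: 40}
    p_value: 1.0e-4
    p_censored: true
  ZNF671:
    carcinoma: {minimum: 0, q25: 25, median: 39, q75: 49, maximum: 72}
    normal:    {minimum: 2, q25: 7,  median: 13, q75: 16, maximum: 20}
    p_value: 1.0e-4
    p_censored: true
  COL6A2:
    carcinoma: {minimum: 0, q25: 12, median: 34, q75: 52, maximum: 66}
    normal:    {minimum: 1, q25: 4,  median: 8,  q75: 10, maximum: 23}
    p_value: 1.0e-4
    p_censored: true
  APC:
    carcinoma: {minimum: 0, q25: 0,  median: 0,  q75: 58, maximum: 92}
    normal:    {minimum: 0, q25: 1,  median: 2,  q75: 25, maximum: 77}
    p_value: 0.2662
    p_censored: false
    parse_ambiguous: true
  HIST1H3C:
    carcinoma: {minimum: 0, q25: 0,  median: 1,  q75: 5,  maximum: 8}
    normal:    {minimum: 0, q25: 0,  median: 1,  q75: 3,  maximum: 8}
    p_value: 0.3959
    p_censored: false
    parse_ambiguous: true
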