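# All-pairs mutual conditional entropy, heatmap and association network
# (edges where 1 - MCE > 0.2), per gender stratum.
input:
  path: data.csv
  items: [Q1, Q2, Q3, Q4, Q5, Q6, Q7, Q8, Q9, Q10]
  covariate_columns: [gender, age, country]
filters:
  country: US
  age: [15, 18]
  gender: [m, f]
analysis:
  strata: [gender]
  threshold: 0.2
output:
  dir: out/mce
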