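# Row-wise conditional-entropy profiles of Q1 given Q7 (positive) and Q9
# (negative), stratified by gender, with 95% resampling intervals.
input:
  path: data.csv
  items: [Q1, Q2, Q3, Q4, Q5, Q6, Q7, Q8, Q9, Q10]
  covariate_columns: [gender, age, country]
  missing_code: "0"
filters:
  country: US
  age: [15, 18]
  gender: [m, f]
  missing_policy: pairwise
analysis:
  response: Q1
  covariates: [Q7, Q9]
  strata: [gender]
  base: null          # natural log (nats); use 2 for bits
  ci: {M: 1000, level: 0.95, seed: 1}
output:
  dir: out/profile
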