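# Laboratory default parameter set for the Coelopa frigida inversion model.
# Relative survival (S) and reproductive success (T) per genotype (AA, AB, BB),
# global viability V, fecundity E, development-time means (days) and the
# habitat-availability window (days).

[fitness]
survival_female = [0.71, 0.90, 1.0]
survival_male = [0.81, 1.0, 0.88]
reproduction_female = [1.0, 0.97, 0.87]
reproduction_male = [1.0, 0.55, 0.1]
viability = 0.3
fecundity = 70

[development]
mean_female = [9.0, 8.7, 9.0]
mean_male = [12.8, 10.3, 8.8]
variation = 0.5

[habitat]
a_mean = 30.0
a_var = 2.0

[simulation]
carrying_capacity = 1000
n_generations = 5
p0 = 0.32
sex_ratio = 0.5
n_replicates = 30
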