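{
 "description": "Best genome from this package's constrained evolutionary searches (inhibitory AIY->AIZ decoding); selected as the highest Gaussian-plate CI among run-best individuals whose ASER->AIY weights are both inhibitory.",
 "search": {
  "population": 60,
  "elite": 20,
  "generations": 150,
  "fitness_trials": 10,
  "t_sim_evolution": 500.0,
  "constrain_aiy_aiz": true,
  "seed": 22
 },
 "evolution_fitness": 0.768,
 "gaussian_ci_20_trials": 0.869,
 "genome": [
  -1.0,
  0.32638336419156994,
  0.8078887013500712,
  1.0,
  -0.526922785076359,
  -0.9182861656391086,
  -0.06452155896304627,
  0.23401213366028398,
  0.4581598202403167,
  0.8599717873441178,
  0.8749682831889983,
  0.8532194546280799,
  0.08585655647953591,
  -0.9201756627211355,
  -0.6127445630656927,
  0.6040027333960555,
  0.04357535011793306,
  1.0,
  -0.4045020940045735,
  0.5600543863906193,
  0.1320702031653004,
  0.37934730358621177
 ]
}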