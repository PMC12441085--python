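{
 "schema": 1,
 "name": "table6_seir_variant",
 "compartments": [
  "S",
  "E",
  "A",
  "I",
  "R"
 ],
 "parameters": {
  "beta_1": "rate",
  "beta_2": "rate",
  "gamma": "rate",
  "sigma": "rate",
  "mu": "rate"
 },
 "transitions": [
  {
   "name": "infect_a",
   "rate": "beta_1"
  },
  {
   "name": "infect_i",
   "rate": "beta_2"
  },
  {
   "name": "progress",
   "rate": "gamma"
  },
  {
   "name": "worsen",
   "rate": "sigma"
  },
  {
   "name": "remove_a",
   "rate": "mu"
  },
  {
   "name": "remove_i",
   "rate": "mu"
  }
 ],
 "arcs": [
  {
   "source": "S",
   "target": "infect_a"
  },
  {
   "source": "A",
   "target": "infect_a"
  },
  {
   "source": "infect_a",
   "target": "E"
  },
  {
   "source": "infect_a",
   "target": "A"
  },
  {
   "source": "S",
   "target": "infect_i"
  },
  {
   "source": "I",
   "target": "infect_i"
  },
  {
   "source": "infect_i",
   "target": "E"
  },
  {
   "source": "infect_i",
   "target": "I"
  },
  {
   "source": "E",
   "target": "progress"
  },
  {
   "source": "progress",
   "target": "A"
  },
  {
   "source": "A",
   "target": "worsen"
  },
  {
   "source": "worsen",
   "target": "I"
  },
  {
   "source": "A",
   "target": "remove_a"
  },
  {
   "source": "remove_a",
   "target": "R"
  },
  {
   "source": "I",
   "target": "remove_i"
  },
  {
   "source": "remove_i",
   "target": "R"
  }
 ],
 "km_partition": {
  "susceptible": {
   "compartments": [
    "S"
   ],
   "transitions": []
  },
  "infection_process": {
   "compartments": [],
   "transitions": [
    "infect_a",
    "infect_i"
   ]
  },
  "infection": {
   "compartments": [
    "E",
    "A",
    "I"
   ],
   "transitions": [
    "progress",
    "worsen",
    "remove_a",
    "remove_i"
   ]
  }
 },
 "dfe": {
  "mode": "keep-symbolic"
 },
 "golden": {
  "ode": {
   "S": "-beta_1*S*A - beta_2*S*I",
   "E": "beta_1*S*A + beta_2*S*I - gamma*E",
   "A": "gamma*E - (sigma+mu)*A",
   "I": "sigma*A - mu*I",
   "R": "mu*A + mu*I"
  },
  "F": [
   [
    "0",
    "beta_1*S",
    "beta_2*S"
   ],
   [
    "0",
    "0",
    "0"
   ],
   [
    "0",
    "0",
    "0"
   ]
  ],
  "V": [
   [
    "gamma",
    "0",
    "0"
   ],
   [
    "-gamma",
    "mu+sigma",
    "0"
   ],
   [
    "0",
    "-sigma",
    "mu"
   ]
  ],
  "K": [
   [
    "beta_1*S/(mu+sigma) + beta_2*sigma*S/((mu+sigma)*mu)",
    "beta_1*S/(mu+sigma) + beta_2*sigma*S/((mu+sigma)*mu)",
    "beta_2*S/mu"
   ],
   [
    "0",
    "0",
    "0"
   ],
   [
    "0",
    "0",
    "0"
   ]
  ],
  "R0": "beta_1*S/(mu+sigma) + beta_2*sigma*S/((mu+sigma)*mu)",
  "flags": {
   "assumption7_clean": true,
   "single_nonzero_eigenvalue": true,
   "closed_population": false,
   "demographic": false
  }
 }
}
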