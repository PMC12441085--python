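{
 "schema": 1,
 "name": "siwr",
 "compartments": [
  "S",
  "I",
  "W",
  "R"
 ],
 "parameters": {
  "mu": "rate",
  "N": "quantity",
  "beta_I": "rate",
  "beta_W": "rate",
  "alpha": "rate",
  "gamma": "rate",
  "xi": "rate"
 },
 "transitions": [
  {
   "name": "birth",
   "rate": "mu*N"
  },
  {
   "name": "death_S",
   "rate": "mu"
  },
  {
   "name": "infect_i",
   "rate": "beta_I"
  },
  {
   "name": "infect_w",
   "rate": "beta_W"
  },
  {
   "name": "shed",
   "rate": "alpha"
  },
  {
   "name": "recover",
   "rate": "gamma"
  },
  {
   "name": "decay",
   "rate": "xi"
  },
  {
   "name": "death_I",
   "rate": "mu"
  },
  {
   "name": "death_R",
   "rate": "mu"
  }
 ],
 "arcs": [
  {
   "source": "birth",
   "target": "S"
  },
  {
   "source": "S",
   "target": "death_S"
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
   "target": "I",
   "multiplicity": 2
  },
  {
   "source": "S",
   "target": "infect_w"
  },
  {
   "source": "W",
   "target": "infect_w"
  },
  {
   "source": "infect_w",
   "target": "I"
  },
  {
   "source": "infect_w",
   "target": "W"
  },
  {
   "source": "I",
   "target": "shed"
  },
  {
   "source": "shed",
   "target": "I"
  },
  {
   "source": "shed",
   "target": "W"
  },
  {
   "source": "I",
   "target": "recover"
  },
  {
   "source": "recover",
   "target": "R"
  },
  {
   "source": "W",
   "target": "decay"
  },
  {
   "source": "I",
   "target": "death_I"
  },
  {
   "source": "R",
   "target": "death_R"
  }
 ],
 "km_partition": {
  "susceptible": {
   "compartments": [
    "S"
   ],
   "transitions": [
    "birth",
    "death_S"
   ]
  },
  "infection_process": {
   "compartments": [],
   "transitions": [
    "infect_i",
    "infect_w"
   ]
  },
  "infection": {
   "compartments": [
    "I",
    "W"
   ],
   "transitions": [
    "shed",
    "recover",
    "decay",
    "death_I"
   ]
  }
 },
 "dfe": {
  "mode": "keep-symbolic"
 },
 "golden": {
  "ode": {
   "S": "mu*N - beta_W*S*W - beta_I*S*I - mu*S",
   "I": "beta_W*S*W + beta_I*S*I - (gamma+mu)*I",
   "W": "alpha*I - xi*W",
   "R": "gamma*I - mu*R"
  },
  "F": [
   [
    "beta_I*S",
    "beta_W*S"
   ],
   [
    "0",
    "0"
   ]
  ],
  "V": [
   [
    "gamma+mu",
    "0"
   ],
   [
    "-alpha",
    "xi"
   ]
  ],
  "K": [
   [
    "beta_I*S/(gamma+mu) + alpha*beta_W*S/((gamma+mu)*xi)",
    "beta_W*S/xi"
   ],
   [
    "0",
    "0"
   ]
  ],
  "R0": "beta_I*S/(gamma+mu) + alpha*beta_W*S/((gamma+mu)*xi)",
  "flags": {
   "assumption7_clean": false,
   "single_nonzero_eigenvalue": true,
   "closed_population": false,
   "demographic": false,
   "g4_conditional": true
  }
 }
}
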