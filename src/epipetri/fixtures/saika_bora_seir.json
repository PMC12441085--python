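{
 "schema": 1,
 "name": "saika_bora_seir",
 "compartments": [
  "S",
  "E",
  "I",
  "R"
 ],
 "parameters": {
  "Lambda": "rate",
  "mu": "rate",
  "beta": "rate",
  "beta_p": "rate",
  "eta": "rate",
  "alpha": "rate"
 },
 "transitions": [
  {
   "name": "birth",
   "rate": "Lambda"
  },
  {
   "name": "death_S",
   "rate": "mu"
  },
  {
   "name": "infect",
   "rate": "beta"
  },
  {
   "name": "infect_direct",
   "rate": "beta_p"
  },
  {
   "name": "progress",
   "rate": "eta"
  },
  {
   "name": "recover",
   "rate": "alpha"
  },
  {
   "name": "death_E",
   "rate": "mu"
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
   "target": "infect"
  },
  {
   "source": "I",
   "target": "infect"
  },
  {
   "source": "infect",
   "target": "E"
  },
  {
   "source": "infect",
   "target": "I"
  },
  {
   "source": "S",
   "target": "infect_direct"
  },
  {
   "source": "I",
   "target": "infect_direct"
  },
  {
   "source": "infect_direct",
   "target": "I",
   "multiplicity": 2
  },
  {
   "source": "E",
   "target": "progress"
  },
  {
   "source": "progress",
   "target": "I"
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
   "source": "E",
   "target": "death_E"
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
    "infect",
    "infect_direct"
   ]
  },
  "infection": {
   "compartments": [
    "E",
    "I"
   ],
   "transitions": [
    "progress",
    "recover",
    "death_E",
    "death_I"
   ]
  }
 },
 "dfe": {
  "mode": "keep-symbolic"
 },
 "golden": {
  "ode": {
   "S": "Lambda - (beta+beta_p)*S*I - mu*S",
   "E": "beta*S*I - (eta+mu)*E",
   "I": "eta*E - (alpha+mu)*I + beta_p*S*I",
   "R": "alpha*I - mu*R"
  },
  "F": [
   [
    "0",
    "beta*S"
   ],
   [
    "0",
    "beta_p*S"
   ]
  ],
  "V": [
   [
    "eta+mu",
    "0"
   ],
   [
    "-eta",
    "alpha+mu"
   ]
  ],
  "K": [
   [
    "beta*eta*S/((alpha+mu)*(eta+mu))",
    "beta*S/(alpha+mu)"
   ],
   [
    "beta_p*eta*S/((alpha+mu)*(eta+mu))",
    "beta_p*S/(alpha+mu)"
   ]
  ],
  "R0": "beta*eta*S/((alpha+mu)*(eta+mu)) + beta_p*S/(alpha+mu)",
  "flags": {
   "assumption7_clean": true,
   "single_nonzero_eigenvalue": true,
   "closed_population": false,
   "demographic": true,
   "lifecycle_vertices": 2,
   "lifecycle_edges": 5
  }
 }
}
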