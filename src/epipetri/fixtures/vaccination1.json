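{
 "schema": 1,
 "name": "vaccination1",
 "compartments": [
  "S",
  "I",
  "R"
 ],
 "parameters": {
  "beta": "rate",
  "alpha": "rate",
  "mu": "rate",
  "p": "probability",
  "q": "probability",
  "N": "quantity"
 },
 "transitions": [
  {
   "name": "recruit",
   "rate": "mu*N"
  },
  {
   "name": "infect",
   "rate": "beta"
  },
  {
   "name": "recover",
   "rate": "alpha"
  },
  {
   "name": "death_S",
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
   "source": "recruit",
   "target": "S",
   "weight": "q"
  },
  {
   "source": "recruit",
   "target": "R",
   "weight": "p"
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
   "target": "I",
   "multiplicity": 2
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
   "source": "S",
   "target": "death_S"
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
    "recruit",
    "death_S"
   ]
  },
  "infection_process": {
   "compartments": [],
   "transitions": [
    "infect"
   ]
  },
  "infection": {
   "compartments": [
    "I"
   ],
   "transitions": [
    "recover",
    "death_I"
   ]
  }
 },
 "dfe": {
  "mode": "symbolic-solve"
 },
 "golden": {
  "ode": {
   "S": "q*mu*N - beta*S*I - mu*S",
   "I": "beta*S*I - (mu+alpha)*I",
   "R": "p*mu*N + alpha*I - mu*R"
  },
  "F": [
   [
    "beta*q*N"
   ]
  ],
  "V": [
   [
    "mu+alpha"
   ]
  ],
  "K": [
   [
    "beta*q*N/(mu+alpha)"
   ]
  ],
  "R0": "beta*q*N/(mu+alpha)",
  "flags": {
   "assumption7_clean": true,
   "single_nonzero_eigenvalue": true,
   "closed_population": false,
   "demographic": true
  }
 }
}
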