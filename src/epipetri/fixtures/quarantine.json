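{
 "schema": 1,
 "name": "quarantine",
 "compartments": [
  "S",
  "I",
  "Q",
  "R"
 ],
 "parameters": {
  "Lambda": "rate",
  "mu": "rate",
  "beta": "rate",
  "alpha": "rate",
  "gamma": "rate",
  "eta": "rate",
  "A": "quantity"
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
   "rate": "beta/A"
  },
  {
   "name": "recover",
   "rate": "alpha"
  },
  {
   "name": "isolate",
   "rate": "gamma"
  },
  {
   "name": "release",
   "rate": "eta"
  },
  {
   "name": "death_I",
   "rate": "mu"
  },
  {
   "name": "death_Q",
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
   "source": "I",
   "target": "isolate"
  },
  {
   "source": "isolate",
   "target": "Q"
  },
  {
   "source": "Q",
   "target": "release"
  },
  {
   "source": "release",
   "target": "R"
  },
  {
   "source": "I",
   "target": "death_I"
  },
  {
   "source": "Q",
   "target": "death_Q"
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
    "infect"
   ]
  },
  "infection": {
   "compartments": [
    "I",
    "Q"
   ],
   "transitions": [
    "recover",
    "isolate",
    "release",
    "death_I",
    "death_Q"
   ]
  }
 },
 "dfe": {
  "mode": "keep-symbolic",
  "substitutions": {
   "A": "1"
  }
 },
 "golden": {
  "ode": {
   "S": "Lambda - beta*S*I/A - mu*S",
   "I": "beta*S*I/A - (alpha+gamma+mu)*I",
   "Q": "gamma*I - (eta+mu)*Q",
   "R": "alpha*I + eta*Q - mu*R"
  },
  "F": [
   [
    "beta*S",
    "0"
   ],
   [
    "0",
    "0"
   ]
  ],
  "V": [
   [
    "alpha+gamma+mu",
    "0"
   ],
   [
    "-gamma",
    "eta+mu"
   ]
  ],
  "K": [
   [
    "beta*S/(alpha+gamma+mu)",
    "0"
   ],
   [
    "0",
    "0"
   ]
  ],
  "R0": "beta*S/(alpha+gamma+mu)",
  "flags": {
   "assumption7_clean": true,
   "single_nonzero_eigenvalue": true,
   "closed_population": false,
   "demographic": true
  }
 }
}
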