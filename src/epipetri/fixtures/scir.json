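{
 "schema": 1,
 "name": "scir",
 "compartments": [
  "S",
  "C",
  "I",
  "R"
 ],
 "parameters": {
  "Lambda": "rate",
  "mu": "rate",
  "beta": "rate",
  "q": "probability",
  "eta": "rate",
  "gamma": "rate",
  "alpha": "rate",
  "rho": "rate"
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
   "name": "infect_c",
   "rate": "q*beta"
  },
  {
   "name": "progress",
   "rate": "eta"
  },
  {
   "name": "recover_c",
   "rate": "gamma"
  },
  {
   "name": "recover_i",
   "rate": "alpha"
  },
  {
   "name": "relapse",
   "rate": "rho"
  },
  {
   "name": "death_C",
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
   "target": "C"
  },
  {
   "source": "infect",
   "target": "I"
  },
  {
   "source": "S",
   "target": "infect_c"
  },
  {
   "source": "C",
   "target": "infect_c"
  },
  {
   "source": "infect_c",
   "target": "C",
   "multiplicity": 2
  },
  {
   "source": "C",
   "target": "progress"
  },
  {
   "source": "progress",
   "target": "I"
  },
  {
   "source": "C",
   "target": "recover_c"
  },
  {
   "source": "recover_c",
   "target": "R"
  },
  {
   "source": "I",
   "target": "recover_i"
  },
  {
   "source": "recover_i",
   "target": "R"
  },
  {
   "source": "R",
   "target": "relapse"
  },
  {
   "source": "relapse",
   "target": "S"
  },
  {
   "source": "C",
   "target": "death_C"
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
    "infect_c"
   ]
  },
  "infection": {
   "compartments": [
    "C",
    "I"
   ],
   "transitions": [
    "progress",
    "recover_c",
    "recover_i",
    "death_C",
    "death_I"
   ]
  }
 },
 "dfe": {
  "mode": "keep-symbolic"
 },
 "golden": {
  "ode": {
   "S": "Lambda - beta*S*(I+q*C) - mu*S + rho*R",
   "C": "beta*S*(I+q*C) - (eta+gamma+mu)*C",
   "I": "eta*C - (alpha+mu)*I",
   "R": "alpha*I + gamma*C - (mu+rho)*R"
  },
  "F": [
   [
    "beta*S*q",
    "beta*S"
   ],
   [
    "0",
    "0"
   ]
  ],
  "V": [
   [
    "eta+gamma+mu",
    "0"
   ],
   [
    "-eta",
    "alpha+mu"
   ]
  ],
  "K": [
   [
    "beta*q*S/(eta+gamma+mu) + beta*eta*S/((alpha+mu)*(eta+gamma+mu))",
    "beta*S/(alpha+mu)"
   ],
   [
    "0",
    "0"
   ]
  ],
  "R0": "beta*q*S/(eta+gamma+mu) + beta*eta*S/((alpha+mu)*(eta+gamma+mu))",
  "flags": {
   "assumption7_clean": true,
   "single_nonzero_eigenvalue": true,
   "closed_population": false,
   "demographic": true
  }
 }
}
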