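{
 "schema": 1,
 "name": "malaria",
 "compartments": [
  "S_H",
  "I_H",
  "R_H",
  "S_M",
  "I_M"
 ],
 "parameters": {
  "Pi": "rate",
  "Lambda": "rate",
  "mu_H": "rate",
  "mu_M": "rate",
  "beta_HM": "rate",
  "beta_MH": "rate",
  "alpha": "rate",
  "delta": "rate",
  "sigma": "rate"
 },
 "constraints": {
  "alpha": "delta + alpha_excess"
 },
 "transitions": [
  {
   "name": "birth_H",
   "rate": "Pi"
  },
  {
   "name": "death_SH",
   "rate": "mu_H"
  },
  {
   "name": "infect_H",
   "rate": "beta_HM"
  },
  {
   "name": "removal_H",
   "rate": "alpha - delta"
  },
  {
   "name": "death_IH",
   "rate": "mu_H"
  },
  {
   "name": "recover_H",
   "rate": "sigma"
  },
  {
   "name": "death_RH",
   "rate": "mu_H"
  },
  {
   "name": "birth_M",
   "rate": "Lambda"
  },
  {
   "name": "death_SM",
   "rate": "mu_M"
  },
  {
   "name": "infect_M",
   "rate": "beta_MH"
  },
  {
   "name": "death_IM",
   "rate": "mu_M"
  }
 ],
 "arcs": [
  {
   "source": "birth_H",
   "target": "S_H"
  },
  {
   "source": "S_H",
   "target": "death_SH"
  },
  {
   "source": "S_H",
   "target": "infect_H"
  },
  {
   "source": "I_M",
   "target": "infect_H"
  },
  {
   "source": "infect_H",
   "target": "I_H"
  },
  {
   "source": "infect_H",
   "target": "I_M"
  },
  {
   "source": "I_H",
   "target": "removal_H"
  },
  {
   "source": "I_H",
   "target": "death_IH"
  },
  {
   "source": "I_H",
   "target": "recover_H"
  },
  {
   "source": "recover_H",
   "target": "R_H"
  },
  {
   "source": "R_H",
   "target": "death_RH"
  },
  {
   "source": "birth_M",
   "target": "S_M"
  },
  {
   "source": "S_M",
   "target": "death_SM"
  },
  {
   "source": "S_M",
   "target": "infect_M"
  },
  {
   "source": "I_H",
   "target": "infect_M"
  },
  {
   "source": "infect_M",
   "target": "I_M"
  },
  {
   "source": "infect_M",
   "target": "I_H"
  },
  {
   "source": "I_M",
   "target": "death_IM"
  }
 ],
 "km_partition": {
  "susceptible": {
   "compartments": [
    "S_H",
    "S_M"
   ],
   "transitions": [
    "birth_H",
    "death_SH",
    "birth_M",
    "death_SM"
   ]
  },
  "infection_process": {
   "compartments": [],
   "transitions": [
    "infect_H",
    "infect_M"
   ]
  },
  "infection": {
   "compartments": [
    "I_H",
    "I_M"
   ],
   "transitions": [
    "removal_H",
    "death_IH",
    "recover_H",
    "death_IM"
   ]
  }
 },
 "dfe": {
  "mode": "keep-symbolic"
 },
 "golden": {
  "ode": {
   "S_H": "Pi - beta_HM*S_H*I_M - mu_H*S_H",
   "I_H": "beta_HM*S_H*I_M - (mu_H+sigma)*I_H - (alpha-delta)*I_H",
   "R_H": "sigma*I_H - mu_H*R_H",
   "S_M": "Lambda - beta_MH*S_M*I_H - mu_M*S_M",
   "I_M": "beta_MH*S_M*I_H - mu_M*I_M"
  },
  "F": [
   [
    "0",
    "beta_HM*S_H"
   ],
   [
    "beta_MH*S_M",
    "0"
   ]
  ],
  "V": [
   [
    "alpha - delta + mu_H + sigma",
    "0"
   ],
   [
    "0",
    "mu_M"
   ]
  ],
  "K": [
   [
    "0",
    "beta_HM*S_H/mu_M"
   ],
   [
    "beta_MH*S_M/(alpha - delta + mu_H + sigma)",
    "0"
   ]
  ],
  "R0": "(beta_HM*beta_MH*S_H*S_M/((alpha - delta + mu_H + sigma)*mu_M))^(1/2)",
  "flags": {
   "assumption7_clean": true,
   "single_nonzero_eigenvalue": false,
   "closed_population": false,
   "demographic": true
  }
 }
}
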