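code,hazard,subsystem,failure_mode,effect,cause
FM1,Raw water transfer pipeline,pretreatment,"Raw water quality does not meet requirement, such as increased levels of particulates, bacteria, organic matter, minerals, etc.","Inefficiency of the pretreatment system in removing microbial and particulate contaminants leads to increased impurity load on downstream RO, resulting in organic and microbial contamination of the RO, decreased microbial filtration efficiency, and has potential impact on the microbial and endotoxin levels in the product water.","Water supply pipeline repairs; rising environmental temperatures, etc."
FM2,Multi-media filter,pretreatment,Unable to filter raw water,"Reduced water output, unable to meet the demand of water input of subsequent filters, affecting water production; biofilm formed on its surface accelerates fouling of downstream RO system, decreasing microbial filtration efficiency and potentially affecting the microbial and endotoxin levels in the product water.",Delayed replacement of filter media leading to biofilm formation; ineffective disinfection and backwashing of the filter causing clogging.
FM3,Activated carbon filter,pretreatment,Unable to filter raw water,"Inability to remove NOM leads to organic fouling of the RO membrane, affecting filtration efficiency; nutrients provided by NOM promote uncontrolled bacterial growth on the RO membrane, leading to biofouling and potentially affecting the microbial and endotoxin levels in the product water.",Delayed replacement of filter media leading to biofilm formation; ineffective disinfection and backwashing of the filter causing clogging.
FM4,Antiscalant dosing system,pretreatment,"Low concentration of chemicals in the antiscalant dosing tank, unable to remove precipitable ions","Insufficient antiscalant concentration leads to precipitation of ions like calcium, magnesium, and silicon on the RO, damaging the RO membrane and reducing filtration efficiency, thus potentially affecting the microbial and endotoxin levels in the product water.",Malfunction of the antiscalant dosing system
FM5,SMBS dosing system,pretreatment,Low/high dosing of SMBS/SBS,"Degradation of RO membrane, reduced microbial filtration efficiency, thus potentially affecting the microbial and endotoxin levels in the product water.",Malfunction of the SMBS dosing system
FM6,High-pressure pump,production,Water pressure may not be sufficient to feed RO,"The RO system is unable to remove inorganic, organic, and microbial impurities, likely affecting the microbial and endotoxin levels in the product water.",High-pressure pump malfunction
FM7,RO,production,Leakage of the RO membrane,"Causes bypass contamination, likely affecting the microbial and endotoxin levels in the product water.",Delayed maintenance of the RO; failure of O-ring seals; degradation and failure due to aging of the RO system.
FM8,RO,production,Damage to RO membrane,"Inability to remove inorganic, organic, and microbial impurities, likely affecting the microbial and endotoxin levels in the product water.","Delayed maintenance of the RO; pressure, temperature, chemical agents, microbial metabolites, etc. causing membrane degradation; improper thermal disinfection and chemical cleaning; or inadequate chlorine removal causing membrane damage."
FM9,RO,production,Scaling/fouling of RO membrane,"Reduced efficiency in removing inorganic, organic, and microbial impurities, potentially impacting the microbial and endotoxin levels in the product water.",Frequent RO use or inadequate disinfection leading to clogging or poor feed water
FM10,CEDI,production,CEDI cannot provide electric field,"CEDI malfunction causes the anion and cation membranes and resins to become a breeding ground for microorganisms, likely affecting the microbial and endotoxin levels in the product water.",CEDI malfunction
FM11,CEDI,production,Leakage of CEDI membrane,"Failure of membrane sealing leads to leakage of concentrate into the permeate water, causing product water contamination, likely affecting the microbial and endotoxin levels in the product water.",Improper pressure balance or water hammer causing membrane sealing failure in the CEDI.
FM12,UF,storage/distribution,Leakage of UF,"Causes bypass contamination, directly affecting the microbial and endotoxin levels in the product water.","Delayed maintenance of the UF system; pressure, temperature, chemical agents, microbial metabolites, etc. causing membrane degradation."
FM13,UF,storage/distribution,Damage to UF membrane,"Inability to remove microorganisms and endotoxins, directly affecting the microbial and endotoxin levels in the product water.","Delayed maintenance of the UF system; pressure, temperature, chemical agents, microbial metabolites, etc. causing membrane degradation; improper chemical cleaning causing damage."
FM14,UF,storage/distribution,Fouling of UF,"Provides an environment for microbial growth, becoming a source of microbial contamination for the distribution system, directly affecting the microbial and endotoxin levels in the product water.","UF intercepts substances becoming nutrients for viable bacteria, leading to microbial growth on the membrane surface and biofilm formation."
FM15,Vent filter,storage/distribution,Unable to remove microorganisms in the air,"Introduction of bacteria from outside to the storage tank, likely affecting the microbial and endotoxin levels in the product water.",Leakage or damage of the vent filter
FM16,Heat exchanger,storage/distribution,Insufficient sealing,"Introduction of bacteria from outside to the storage tank and distribution pipeline, may affect the microbial and endotoxin levels in the product water.",Leakage of the heat exchanger
FM17,Distribution pipeline,storage/distribution,Unpolished pipeline,"Biofilm formation on the pipeline surface, increased microbial count in the distribution pipeline, likely affecting the microbial and endotoxin levels in the product water.",Pipeline not polished after welding or inadequate polishing
FM18,Distribution pump,storage/distribution,Insufficient pump power,"Low flow velocity in the distribution pipeline leads to microbial growth, likely affecting the microbial and endotoxin levels in the product water.",Pump malfunction
FM19,Pipeline welding,storage/distribution,Inadequate welding leading to pipeline leakage,"Introduction of bacteria from outside to the distribution pipeline, directly affecting the microbial and endotoxin levels in the product water.",Poor welding
FM20,Material of construction (MOC),storage/distribution,Materials with water solubility,"Leaching of materials from tanks, pipelines, etc. leads to microbial growth, directly affecting the microbial and endotoxin levels in the product water, especially during system disinfection.","Tanks, pipelines, etc. not using GMP-grade materials"
FM21,Disinfection system,storage/distribution,Inability to sanitize the system; ineffective disinfection; infrequent disinfection,Directly affects the microbial and endotoxin levels in the product water.,"Malfunction of UV system, thermal sanitation unit or ozone system"
FM22,PLC system,auxiliary,Critical equipment process parameters cannot be monitored,May affect the microbial and endotoxin levels in the product water.,System malfunction
FM23,Measuring instruments,auxiliary,Water quality cannot be measured,May affect the microbial and endotoxin levels in the product water.,Instruments malfunction
FM24,Calibration instruments,auxiliary,Measuring instruments cannot be calibrated,May affect the microbial and endotoxin levels in the product water.,Instruments malfunction
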