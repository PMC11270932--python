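region,year,pop_ge60,pop_ge65,density_ge60,density_ge65,prop_ge60,prop_ge65,dep_ratio_ge65,bed_occupancy,daily_visits_per_doctor,daily_inpatients_per_doctor,visits_per_capita,total_expenditure,per_capita_cost,oop_share,n_hospitals,hospital_beds,hospital_technicians,primary_institutions,primary_beds,primary_technicians
china,2012,19390,12714,20.21,13.24,14.3,9.4,12.7,82.80,7.20,2.6,5.1,28119.00,2068.76,44.0,23170,416.15,405.8,912620,132.43,205.2
china,2013,20243,13161,21.09,13.71,14.9,9.7,13.1,82.40,7.30,2.6,5.4,31668.95,2316.23,33.9,24709,457.86,442.5,915368,134.99,213.8
china,2014,21242,13755,22.13,14.33,15.5,10.1,13.7,81.60,7.50,2.6,5.6,35312.40,2565.45,31.99,25860,496.12,474.2,917335,138.12,217.2
china,2015,22200,14386,23.13,14.96,16.1,10.5,14.3,79.50,7.30,2.6,5.6,40974.64,2962.18,29.27,27587,533.06,507.1,920770,141.38,225.8
china,2016,23086,15003,24.05,15.63,16.7,10.8,15.0,79.80,7.30,2.6,5.7,46344.88,3328.61,28.78,29140,568.89,541.5,926518,144.19,235.4
china,2017,24090,15831,25.10,16.49,17.3,11.4,15.9,79.70,7.10,2.6,5.9,52598.28,3756.72,28.77,31056,612.05,578.8,933024,152.85,250.5
china,2018,24949,16658,25.99,17.35,17.9,11.9,16.8,78.80,7.00,2.5,6,59121.91,4206.74,43.60,33009,651.97,612.9,943639,158.36,268.3
china,2019,25388,17603,26.45,18.34,18.1,12.6,17.8,78.02,7.10,2.5,6.24,65841.39,4669.34,28.36,34354,686.65,648.7,954390,163.11,292.1
china,2020,26402,19064,27.50,19.86,18.7,13.5,19.7,67.65,5.90,2.2,5.5,72175.00,5112.34,27.65,35394,713.12,677.5,970036,164.94,312.4
china,2021,26736,20056,27.85,20.89,18.9,14.2,20.8,69.28,6.50,2.2,6,76844.99,5439.97,27.60,36570,741.42,711.5,977790,169.98,330.2
china,2022,28004,20978,29.17,21.85,19.8,14.9,21.8,66.10,6.20,2.1,6,85327.49,6044.09,26.89,36976,766.29,735.3,979768,175.11,345.0
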